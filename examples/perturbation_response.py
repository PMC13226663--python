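"""Quantify a perturbation: signal loss over loci, peak loss, and expression.

Simulates a depletion experiment in which 77% of RING1B-marked loci lose
ChIP signal, tests the decrease with a paired one-tailed Wilcoxon, counts
lost peaks, and runs the differential-expression stand-in on simulated
counts to pull out up/down splits and the strictly-more-than-twofold rule.
"""

from condenscan.perturbation_stats import (
    count_peak_changes,
    define_totipotency_genes,
    differential_expression,
    fraction_changed,
    region_signal,
    updown_fractions,
    wilcoxon_one_tailed,
)
from condenscan.genomic_io import PeakSet
from condenscan.synthetic_data import (
    SimulationConfig,
    make_blueprint,
    simulate_counts,
    simulate_perturbed_chip,
)

config = SimulationConfig(seed=0, dispersion=0.01)
blueprint = make_blueprint(config)

before, after, affected = simulate_perturbed_chip(
    blueprint, config, mark="RING1B", decrease_fraction=0.77
)
regions = [l.interval for l in blueprint if l.marks["RING1B"]]
sig_before = region_signal(before, regions)
sig_after = region_signal(after, regions)

test = wilcoxon_one_tailed(sig_before, sig_after, alternative="less")
frac = fraction_changed(sig_before, sig_after, direction="decrease")
print(f"one-tailed Wilcoxon (decrease) over {test.n} loci: p = {test.p_value:.3g}")
print(f"fraction of loci with decreased signal: {frac['fraction']:.2f} "
      f"({frac['n_changed']}/{frac['n_total']})")

# peak bookkeeping: loci scaled to 30% signal still exceed a lenient
# threshold here, so emulate peak loss by dropping the affected loci
kept = PeakSet([l.interval for l in blueprint
                if l.marks["RING1B"] and l.locus_id not in set(affected)])
full = PeakSet(regions)
changes = count_peak_changes(full, kept)
print(f"peaks before/after: {changes['n_before']}/{changes['n_after']}, "
      f"lost {changes['n_lost']}, gained {changes['n_gained']}")

counts = simulate_counts(blueprint, config)
de = differential_expression(counts, "WT", "KO")
repressed = {l.locus_id for l in blueprint
             if l.class_label == "RYBP_WDR5_RING1B"}
split = updown_fractions(de, repressed)
print(f"among significantly changed repressed-class genes: "
      f"{split['frac_up']:.0%} up, {split['frac_down']:.0%} down")
# Derepression on depletion: genes at repressive condensate loci go up.

up_genes = define_totipotency_genes(de, fold=2)
print(f"genes significantly up strictly more than twofold: {len(up_genes)}")
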