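"""Co-occupancy classification of loci from ChIP peak sets.

Simulates peak sets for the full mark panel, then reproduces the
co-occupancy taxonomies: active vs repressive RYBP loci, the RING1B-lacked /
RING1B-enriched partition of RYBP+WDR5 regions, and promoter classes.
"""

from condenscan.locus_classification import (
    annotate_promoter_classes,
    classify_rybp_loci,
    partition_by_ring1b,
    peak_overlap_ratio,
)
from condenscan.synthetic_data import (
    SimulationConfig,
    genes_from_blueprint,
    make_blueprint,
    simulate_chip,
)

config = SimulationConfig(seed=0)
blueprint = make_blueprint(config)
peaks, tracks = simulate_chip(blueprint, config, noiseless=True)

classified = classify_rybp_loci(
    peaks["RYBP"], peaks["H3K4me3"], peaks["H3K27me3"]
)
by_label = {}
for c in classified:
    for label in c.labels:
        by_label[label] = by_label.get(label, 0) + 1
print("RYBP locus classes (active = K4 without K27; repressive = K27):")
print("  ", by_label)

parts = partition_by_ring1b(peaks["RYBP"], peaks["WDR5"], peaks["RING1B"])
print(f"RYBP+WDR5 co-localized regions: "
      f"{len(parts['RING1B_lacked'])} RING1B-lacked, "
      f"{len(parts['RING1B_enriched'])} RING1B-enriched")

ratio = peak_overlap_ratio(peaks["RYBP"], peaks["STAT3"])
print(f"fraction of RYBP peaks overlapping STAT3: "
      f"{ratio.overlap_ratio:.3f} ({ratio.n_overlapping}/{ratio.n_query})")
# STAT3 marks the transcriptionally active, RING1B-excluded compartment,
# so it overlaps only the active subset of RYBP peaks.

genes = genes_from_blueprint(blueprint, config)
classes, fractions = annotate_promoter_classes(
    genes, peaks["RYBP"], peaks["H3K4me3"], peaks["H3K27me3"]
)
print("promoter class fractions over RYBP-bound promoters:")
for k in ("promoter_active_of_rybp_bound", "promoter_poised_of_rybp_bound"):
    print(f"  {k}: {fractions[k]:.3f}")
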