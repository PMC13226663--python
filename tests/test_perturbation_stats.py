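from itertools import product

import numpy as np
import pytest
from scipy.stats import rankdata

from condenscan.genomic_io import CountMatrix, CoverageTrack, GenomicInterval, PeakSet
from condenscan.perturbation_stats import (
    count_peak_changes,
    define_totipotency_genes,
    differential_expression,
    fraction_changed,
    region_signal,
    set_overlap_fractions,
    signal_matrix,
    updown_fractions,
    wilcoxon_one_tailed,
)
from condenscan.synthetic_data import (
    SimulationConfig,
    make_blueprint,
    simulate_counts,
    simulate_perturbed_chip,
)

from conftest import occupancy_mask, random_intervals


def track_from(values, bin_size=10):
    arr = np.asarray(values, dtype=float)
    return CoverageTrack(bin_size, {"chr1": arr}, float(arr.sum()))


class TestRegionSignal:
    def test_constant_track(self):
        t = track_from(np.full(100, 3.0))
        regions = PeakSet([GenomicInterval("chr1", 37, 503)])
        assert region_signal(t, regions)[0] == pytest.approx(3.0)

    def test_half_and_half(self):
        t = track_from([2.0] * 5 + [4.0] * 5)
        regions = [GenomicInterval("chr1", 0, 100)]
        assert region_signal(t, regions)[0] == pytest.approx(3.0)

    def test_matches_per_base_oracle(self, rng):
        vals = rng.random(200)
        t = track_from(vals)
        per_base = np.repeat(vals, 10)
        for _ in range(50):
            s = int(rng.integers(0, 1990))
            e = s + int(rng.integers(1, 2000 - s))
            got = region_signal(t, [GenomicInterval("chr1", s, e)])[0]
            assert got == pytest.approx(per_base[s:e].mean(), abs=1e-9)

    def test_off_chromosome_is_error(self):
        t = track_from(np.ones(10))
        with pytest.raises(ValueError):
            region_signal(t, [GenomicInterval("chr1", 50, 200)])


class TestSignalMatrix:
    def test_constant_track_gives_constant_matrix(self):
        t = track_from(np.full(1000, 2.0))
        m = signal_matrix(t, [GenomicInterval("chr1", 4000, 6000)],
                          flank=1000, n_bins=20)
        np.testing.assert_allclose(m.values, 2.0)

    def test_central_spike_lands_in_central_bin(self):
        vals = np.zeros(1000)
        vals[500] = 100.0  # spike at 5000-5010 bp
        t = track_from(vals)
        m = signal_matrix(t, [GenomicInterval("chr1", 4000, 6010)],
                          flank=1000, n_bins=21)
        assert np.argmax(m.values[0]) == 10

    def test_matches_direct_binning_oracle(self, rng):
        vals = rng.random(1000)
        t = track_from(vals)
        per_base = np.repeat(vals, 10)
        region = GenomicInterval("chr1", 3000, 5000)
        m = signal_matrix(t, [region], flank=500, n_bins=10)
        mid = 4000
        edges = np.linspace(mid - 500, mid + 500, 11).round().astype(int)
        oracle = [per_base[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
        np.testing.assert_allclose(m.values[0], oracle, atol=1e-9)

    def test_edge_region_zero_padded_with_warning(self):
        t = track_from(np.ones(10))
        with pytest.warns(UserWarning, match="zero-padding"):
            m = signal_matrix(t, [GenomicInterval("chr1", 0, 20)],
                              flank=50, n_bins=4)
        assert m.values[0][0] == 0.0  # window reaches before base 0

    def test_region_scaled_anchor(self):
        vals = np.concatenate([np.zeros(50), np.ones(50)])
        t = track_from(vals)
        m = signal_matrix(t, [GenomicInterval("chr1", 0, 1000)],
                          n_bins=10, anchor="region_scaled")
        np.testing.assert_allclose(m.values[0], [0] * 5 + [1] * 5, atol=1e-9)


class TestWilcoxon:
    def test_uniform_shift_exact_minimum_p(self):
        before = np.arange(10.0)
        r = wilcoxon_one_tailed(before, before + 1, alternative="greater")
        assert r.p_value == pytest.approx(1 / 1024)

    def test_identical_inputs_give_p_one(self):
        x = np.arange(8.0)
        with pytest.warns(UserWarning, match="zero"):
            r = wilcoxon_one_tailed(x, x, alternative="greater")
        assert r.p_value == 1.0

    def test_exact_equals_sign_flip_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 13))
            before = rng.normal(size=n)
            after = before + rng.normal(size=n)
            alt = "greater" if rng.random() < 0.5 else "less"
            r = wilcoxon_one_tailed(before, after, alternative=alt)
            d = after - before
            d = d[d != 0]
            if alt == "less":
                d = -d
            ranks = rankdata(np.abs(d))
            w = ranks[d > 0].sum()
            count = sum(
                1
                for signs in product((0, 1), repeat=len(d))
                if np.dot(signs, ranks) >= w - 1e-12
            )
            assert r.p_value == pytest.approx(count / 2 ** len(d), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_tailed(np.arange(6.0), np.arange(7.0))

    def test_unpaired_variant_runs(self, rng):
        before = rng.normal(0, 1, 50)
        after = rng.normal(1, 1, 50)
        r = wilcoxon_one_tailed(before, after, alternative="greater",
                                paired=False)
        assert r.method == "rank-sum"
        assert r.p_value < 0.01

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            before = rng.normal(size=500)
            after = before + rng.normal(size=500)
            r = wilcoxon_one_tailed(before, after, alternative="less")
            rejections += r.p_value < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.03


class TestFractionChanged:
    def test_all_decreased(self):
        out = fraction_changed([3.0, 4.0], [1.0, 2.0])
        assert out["fraction"] == 1.0

    def test_equality_is_not_a_decrease(self):
        out = fraction_changed([3.0, 4.0], [3.0, 2.0])
        assert out["fraction"] == pytest.approx(0.5)

    def test_planted_decrease_fraction_exact(self):
        cfg = SimulationConfig(
            seed=0,
            genome={"chr1": 4_000_000},
            n_loci={"RYBP_WDR5_RING1B": 50, "RYBP_repressive": 50},
        )
        bp = make_blueprint(cfg)
        before, after, affected = simulate_perturbed_chip(
            bp, cfg, mark="RING1B", decrease_fraction=0.77
        )
        marked = [l.interval for l in bp if l.marks["RING1B"]]
        b = region_signal(before, marked)
        a = region_signal(after, marked)
        out = fraction_changed(b, a, direction="decrease")
        assert out["fraction"] == pytest.approx(0.77)


class TestPeakChanges:
    def test_simple_loss(self):
        before = PeakSet([GenomicInterval("chr1", s, s + 10)
                          for s in (0, 100, 200)])
        after = PeakSet([GenomicInterval("chr1", 100, 110)])
        out = count_peak_changes(before, after)
        assert (out["n_lost"], out["n_retained"], out["n_gained"]) == (2, 1, 0)

    def test_identical_sets(self):
        ps = PeakSet([GenomicInterval("chr1", 0, 10)])
        out = count_peak_changes(ps, ps)
        assert out["n_lost"] == 0 and out["n_gained"] == 0

    def test_conservation_and_mask_oracle(self, rng):
        before = PeakSet(random_intervals(rng, 500))
        after = PeakSet(random_intervals(rng, 500))
        out = count_peak_changes(before, after)
        assert out["n_before"] == out["n_lost"] + out["n_retained"]
        mask_after = occupancy_mask(list(after), 100_000, ("chr1", "chr2"))
        retained = sum(
            1 for iv in before if mask_after[iv.chrom][iv.start : iv.end].any()
        )
        assert out["n_retained"] == retained


def nb_counts(rng, means, dispersion, n):
    if dispersion == 0:
        return np.stack([rng.poisson(means) for _ in range(n)], axis=1)
    r = 1.0 / dispersion
    return np.stack(
        [rng.negative_binomial(r, r / (r + means)) for _ in range(n)], axis=1
    )


class TestDifferentialExpression:
    def _matrix(self, a, b):
        n_genes = a.shape[0]
        return CountMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"s{j}" for j in range(a.shape[1] + b.shape[1])],
            np.hstack([a, b]),
            ["A"] * a.shape[1] + ["B"] * b.shape[1],
        )

    def test_identical_groups_find_nothing(self, rng):
        means = rng.lognormal(np.log(100), 1.0, 500)
        a = nb_counts(rng, means, 0.05, 3)
        b = nb_counts(rng, means, 0.05, 3)
        de = differential_expression(self._matrix(a, b), "A", "B")
        assert (de.table["fdr"] < 0.05).sum() <= 5

    def test_planted_fourfold_gene_detected(self, rng):
        means = np.full(500, 100.0)
        fold = np.ones(500)
        fold[0] = 4.0
        a = nb_counts(rng, means, 0.01, 3)
        b = nb_counts(rng, means * fold, 0.01, 3)
        de = differential_expression(self._matrix(a, b), "A", "B")
        assert de.table["fdr"].iloc[0] < 0.05
        assert de.table["log2fc"].iloc[0] > 1.5

    def test_library_scale_invariance(self, rng):
        means = rng.lognormal(np.log(200), 0.5, 300)
        a = nb_counts(rng, means, 0.02, 3)
        b = nb_counts(rng, means, 0.02, 3)
        m1 = self._matrix(a, b)
        scaled = np.hstack([a, b]).astype(float)
        scaled[:, 0] *= 4  # quadruple one library
        m2 = CountMatrix(m1.gene_ids, m1.sample_ids, np.round(scaled),
                         m1.condition_labels)
        de1 = differential_expression(m1, "A", "B")
        de2 = differential_expression(m2, "A", "B")
        np.testing.assert_allclose(
            de1.table["log2fc"], de2.table["log2fc"], atol=0.02
        )

    def test_all_zero_gene_handled(self):
        counts = np.ones((5, 6), dtype=int) * 50
        counts[2] = 0
        cm = CountMatrix([f"g{i}" for i in range(5)],
                         [f"s{j}" for j in range(6)], counts,
                         ["A"] * 3 + ["B"] * 3)
        de = differential_expression(cm, "A", "B")
        assert de.table["p"].iloc[2] == 1.0
        assert de.table["log2fc"].iloc[2] == 0.0

    def test_binomial_variant_available(self, rng):
        means = np.full(100, 100.0)
        a = nb_counts(rng, means, 0.0, 3)
        b = nb_counts(rng, means, 0.0, 3)
        de = differential_expression(self._matrix(a, b), "A", "B",
                                     method="binomial")
        assert ((de.table["p"] > 0) & (de.table["p"] <= 1)).all()

    def test_end_to_end_on_simulated_counts(self):
        cfg = SimulationConfig(seed=0, dispersion=0.01)
        bp = make_blueprint(cfg)
        cm = simulate_counts(bp, cfg)
        de = differential_expression(cm, "WT", "KO")
        planted_up = [l.locus_id for l in bp
                      if l.class_label == "RYBP_WDR5_RING1B"]
        sig_up = de.significant()
        found = sum(1 for g in planted_up
                    if g in sig_up.index and sig_up.loc[g, "log2fc"] > 0)
        assert found / len(planted_up) > 0.9


class TestGeneSetSummaries:
    def _de_from(self, log2fc, fdr):
        import pandas as pd

        from condenscan.perturbation_stats import DEResult

        table = pd.DataFrame(
            {"log2fc": log2fc, "p": fdr, "fdr": fdr},
            index=[f"g{i}" for i in range(len(log2fc))],
        )
        return DEResult(table, np.ones(4), "ESC", "TLSC")

    def test_exact_twofold_excluded(self):
        de = self._de_from([1.0, 1.1, 2.0], [0.001, 0.001, 0.5])
        genes = define_totipotency_genes(de, fold=2)
        # g0 is exactly 2-fold (log2fc 1.0): excluded by the strict rule;
        # g2 is 4-fold but not significant
        assert genes == {"g1"}

    def test_updown_fractions_partition(self):
        de = self._de_from([1.0, -0.5, 2.0, 0.3], [0.01, 0.01, 0.01, 0.9])
        out = updown_fractions(de, {"g0", "g1", "g2", "g3"})
        assert out["n_up"] == 2 and out["n_down"] == 1
        assert out["frac_up"] + out["frac_down"] == pytest.approx(1.0)

    def test_no_significant_members_is_error(self):
        de = self._de_from([1.0], [0.9])
        with pytest.raises(ValueError, match="significant"):
            updown_fractions(de, {"g0"})

    def test_set_overlap_fractions(self, rng):
        universe = {f"g{i}" for i in range(100)}
        a = set(rng.choice(sorted(universe), 30, replace=False))
        b = set(rng.choice(sorted(universe), 40, replace=False))
        out = set_overlap_fractions(a, b, universe)
        brute = sum(1 for g in a if g in b)
        assert out["n_intersection"] == brute
        assert out["frac_a_in_b"] == pytest.approx(brute / 30)
        assert set_overlap_fractions(a, a, universe)["frac_a_in_b"] == 1.0

    def test_empty_a_is_error(self):
        with pytest.raises(ValueError):
            set_overlap_fractions(set(), {"g"}, {"g"})
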