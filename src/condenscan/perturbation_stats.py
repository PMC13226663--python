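"""Signal quantification over locus sets and perturbation statistics.

Covers the comparisons made after a perturbation (protein depletion, fusion
expression, domain mutation): per-region ChIP signal, profile matrices,
paired one-tailed Wilcoxon signed-rank tests, fraction-of-loci-decreased,
peak gain/loss bookkeeping, a moderated-t differential-expression stand-in,
and the derived gene-set summaries (totipotency-gene rule, up/down splits,
set overlaps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import CountMatrix, CoverageTrack, GenomicInterval, PeakSet
from .locus_classification import overlap_flags

__all__ = [
    "SignalMatrix",
    "ComparisonResult",
    "DEResult",
    "region_signal",
    "signal_matrix",
    "wilcoxon_one_tailed",
    "fraction_changed",
    "count_peak_changes",
    "differential_expression",
    "define_totipotency_genes",
    "updown_fractions",
    "set_overlap_fractions",
]


@dataclass
class SignalMatrix:
    """Region x bin mean-signal matrix around an anchor."""

    regions: List[GenomicInterval]
    flank: int
    n_bins: int
    values: np.ndarray

    def profile(self) -> np.ndarray:
        """Column means: the aggregate profile curve."""
        return self.values.mean(axis=0)


@dataclass
class ComparisonResult:
    """Paired before/after comparison of per-region signal."""

    before: np.ndarray
    after: np.ndarray
    p_value: float
    alternative: str
    n: int
    statistic: float
    method: str


@dataclass
class DEResult:
    """Per-gene differential-expression summary (B relative to A)."""

    table: pd.DataFrame  # index gene_id; log2fc, p, fdr, mean_a, mean_b
    size_factors: np.ndarray
    group_a: str
    group_b: str

    @property
    def gene_ids(self) -> List[str]:
        return list(self.table.index)

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr]


# ---------------------------------------------------------------------------
# Signal over regions
# ---------------------------------------------------------------------------


def region_signal(track: CoverageTrack, regions: PeakSet | Sequence[GenomicInterval]) -> np.ndarray:
    """Length-weighted mean track signal over each region."""
    regions = list(regions)
    out = np.empty(len(regions))
    for i, region in enumerate(regions):
        out[i] = _interval_mean(track, region.chrom, region.start, region.end)
    return out


def _interval_mean(
    track: CoverageTrack, chrom: str, start: int, end: int
) -> float:
    """Mean of the piecewise-constant binned signal over [start, end).

    Out-of-chromosome ranges raise; use ``_interval_mean_padded`` for
    zero-padded profile matrices.
    """
    if chrom not in track.values:
        raise ValueError(f"chromosome {chrom} not in track")
    arr = track.values[chrom]
    bs = track.bin_size
    if start < 0 or end > len(arr) * bs:
        raise ValueError(
            f"region {chrom}:{start}-{end} extends beyond the track"
        )
    b0, b1 = start // bs, (end - 1) // bs
    total = 0.0
    for b in range(b0, b1 + 1):
        ov = min(end, (b + 1) * bs) - max(start, b * bs)
        total += arr[b] * ov
    return total / (end - start)


def _interval_mean_padded(
    track: CoverageTrack, chrom: str, start: int, end: int
) -> float:
    """As _interval_mean but bases beyond the chromosome contribute 0."""
    arr = track.values[chrom]
    bs = track.bin_size
    lo = max(start, 0)
    hi = min(end, len(arr) * bs)
    if hi <= lo:
        return 0.0
    inner = _interval_mean(track, chrom, lo, hi)
    return inner * (hi - lo) / (end - start)


def signal_matrix(
    track: CoverageTrack,
    regions: PeakSet | Sequence[GenomicInterval],
    flank: int = 2000,
    n_bins: int = 100,
    anchor: str = "center",
) -> SignalMatrix:
    """Resample signal around each region into ``n_bins`` columns.

    ``anchor="center"`` uses a fixed window of width 2*flank centred on the
    region midpoint (zero-padded with a warning at chromosome edges);
    ``anchor="region_scaled"`` stretches each region body onto the bins.
    Row order follows the input region order; column means give the profile.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if anchor not in ("center", "region_scaled"):
        raise ValueError(f"unknown anchor {anchor!r}")
    region_list = list(regions)
    values = np.zeros((len(region_list), n_bins))
    warned = False
    for i, region in enumerate(region_list):
        if anchor == "center":
            mid = (region.start + region.end) // 2
            lo, hi = mid - flank, mid + flank
            if flank == 0:
                lo, hi = region.start, region.end
        else:
            lo, hi = region.start, region.end
        chrom_len = len(track.values[region.chrom]) * track.bin_size
        if lo < 0 or hi > chrom_len:
            if not warned:
                warnings.warn(
                    "region window extends beyond chromosome; zero-padding",
                    stacklevel=2,
                )
                warned = True
        edges = np.linspace(lo, hi, n_bins + 1)
        for j in range(n_bins):
            a, b = int(round(edges[j])), int(round(edges[j + 1]))
            if b <= a:
                b = a + 1
            values[i, j] = _interval_mean_padded(track, region.chrom, a, b)
    return SignalMatrix(region_list, flank, n_bins, values)


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _signed_rank_exact_p(d: np.ndarray, w_plus: float) -> float:
    """P(W+ >= w_plus) under the exact sign-flip null.

    With untied |d| the null distribution is built by the standard
    rank-polynomial convolution; with ties (midranks) and small n it is
    enumerated over all 2^n sign assignments.
    """
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    if len(np.unique(np.abs(d))) == n:
        # integer ranks: convolution over {include rank r or not}
        total = n * (n + 1) // 2
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in ranks.astype(int):
            counts[r:] += counts[:-r] if r > 0 else 0
        tail = counts[int(np.ceil(w_plus - 1e-12)) :].sum()
        return float(tail / 2**n)
    if n > 20:
        raise ValueError("exact test with ties limited to n <= 20")
    ge = 0
    for signs in product((0.0, 1.0), repeat=n):
        w = float(np.dot(signs, ranks))
        if w >= w_plus - 1e-12:
            ge += 1
    return ge / 2**n


def wilcoxon_one_tailed(
    before: Sequence[float],
    after: Sequence[float],
    alternative: str = "less",
    paired: bool = True,
    method: str = "auto",
) -> ComparisonResult:
    """One-tailed Wilcoxon comparison of paired per-region signals.

    The test is on ``d = after - before``; ``alternative="less"`` tests for a
    decrease after the perturbation, ``"greater"`` for an increase. Zero
    differences are dropped. The exact null distribution is used for
    n <= 25 (enumeration when |d| values tie), otherwise a normal
    approximation with tie and continuity correction. ``paired=False``
    falls back to the unpaired rank-sum test.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after length mismatch")
    if len(before) < 5:
        raise ValueError("need at least 5 paired regions")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    n_regions = len(before)

    if not paired:
        res = stats.mannwhitneyu(after, before, alternative=alternative)
        return ComparisonResult(
            before, after, float(res.pvalue), alternative, n_regions,
            float(res.statistic), "rank-sum",
        )

    d = after - before
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return ComparisonResult(
            before, after, 1.0, alternative, n_regions, 0.0, "degenerate"
        )
    if alternative == "less":
        d = -d  # one-sided test on the reflected differences
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = len(d)
    tied = len(np.unique(np.abs(d))) < n
    if method == "exact" or (method == "auto" and n <= 25 and (not tied or n <= 20)):
        p = _signed_rank_exact_p(d, w_plus)
        used = "signed-rank exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu - 0.5) / sigma  # continuity-corrected upper tail
        p = float(stats.norm.sf(z))
        used = "signed-rank normal approx"
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return ComparisonResult(
        before, after, p, alternative, n_regions, w_plus, used
    )


# ---------------------------------------------------------------------------
# Fractions and peak bookkeeping
# ---------------------------------------------------------------------------


def fraction_changed(
    before: Sequence[float],
    after: Sequence[float],
    direction: str = "decrease",
    min_rel_change: float = 0.0,
) -> Dict[str, float]:
    """Fraction of regions whose signal strictly moved in ``direction``.

    A decrease at region i means ``after_i < before_i * (1 - min_rel_change)``
    (strict; equality is not a change), and symmetrically for increases.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after length mismatch")
    if len(before) == 0:
        raise ValueError("no regions")
    if direction == "decrease":
        changed = after < before * (1.0 - min_rel_change)
    elif direction == "increase":
        changed = after > before * (1.0 + min_rel_change)
    else:
        raise ValueError("direction must be 'decrease' or 'increase'")
    n_changed = int(changed.sum())
    return {
        "fraction": n_changed / len(before),
        "n_changed": n_changed,
        "n_total": len(before),
    }


def count_peak_changes(before: PeakSet, after: PeakSet) -> Dict[str, int]:
    """Peak retention/loss/gain between conditions (>= 1 bp overlap).

    A before-peak is retained iff it overlaps any after-peak; lost
    otherwise; an after-peak overlapping no before-peak is gained. The
    identity n_before = n_lost + n_retained always holds.
    """
    retained = overlap_flags(before, after) if len(before) else np.array([], bool)
    gained = overlap_flags(after, before) if len(after) else np.array([], bool)
    n_retained = int(retained.sum())
    return {
        "n_before": len(before),
        "n_after": len(after),
        "n_retained": n_retained,
        "n_lost": len(before) - n_retained,
        "n_gained": int((~gained).sum()),
    }


# ---------------------------------------------------------------------------
# Differential expression (simplified stand-in)
# ---------------------------------------------------------------------------


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """Per-sample size factors: median ratio to the gene-wise geometric mean."""
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    finite = np.all(np.isfinite(log_counts), axis=1)
    if not finite.any():
        # no gene expressed in every sample: fall back to library totals
        totals = counts.sum(axis=0)
        return totals / np.exp(np.mean(np.log(totals)))
    log_geo = log_counts[finite].mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts[finite] - log_geo, axis=0))
    return factors


def _moderate_variances(
    s2: np.ndarray, df_resid: int, abundance: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances (limma-trend style).

    Observed variances are shrunk toward a prior that follows the
    mean-variance trend (a lowess fit of log s^2 on average log abundance —
    counting noise makes low-abundance genes noisier on the log scale, so a
    constant prior would understate their variance and inflate the far tail
    of the test). The prior degrees of freedom d0 are estimated by matching
    the spread of log s^2 around the trend against the chi-square spread
    expected from df_resid alone. Returns posterior variances and d0.
    """
    ok = s2 > 0
    if ok.sum() < 10:
        return s2, 0.0
    z = np.full_like(s2, np.nan)
    z[ok] = np.log(s2[ok])
    # expected chi-square bias/spread of log s^2 around log sigma^2
    bias = special.digamma(df_resid / 2.0) - np.log(df_resid / 2.0)
    chi_var = float(special.polygamma(1, df_resid / 2.0))
    if abundance is not None and np.ptp(abundance[ok]) > 0:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        fit = lowess(
            z[ok], abundance[ok], frac=0.4, it=2, return_sorted=False
        )
        log_prior = np.empty_like(s2)
        log_prior[ok] = fit - bias
        log_prior[~ok] = np.nanmedian(fit) - bias
        resid_var = float(np.var(z[ok] - fit, ddof=1))
    else:
        e_z = float(np.nanmean(z))
        log_prior = np.full_like(s2, e_z - bias)
        resid_var = float(np.nanvar(z, ddof=1))
    target = resid_var - chi_var
    s0_2 = np.exp(log_prior)
    if target <= 0:
        return s0_2, np.inf
    # invert trigamma(d0/2) = target; trigamma is decreasing
    lo, hi = 1e-3, 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid / 2.0) > target:
            lo = mid
        else:
            hi = mid
    d0 = 0.5 * (lo + hi)
    s0_2 = s0_2 * np.exp(special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    s2_obs = np.where(ok, s2, 0.0)
    s2_mod = (d0 * s0_2 + df_resid * s2_obs) / (d0 + df_resid)
    return s2_mod, d0


def differential_expression(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
    method: str = "moderated_t",
) -> DEResult:
    """Differential expression of condition B relative to condition A.

    A documented simplified stand-in for a full count-model fit: counts are
    normalized by median-of-ratios size factors, and per-gene significance is
    assessed on log2 normalized counts with an empirical-Bayes moderated
    t-statistic (default). ``method="binomial"`` instead applies an exact
    conditional binomial test to pooled normalized counts; that variant
    assumes no biological variance beyond sampling and is anticonservative
    on replicated data (see docs/methods.md). Fold changes are
    ``log2((mean_b + pc) / (mean_a + pc))`` on the normalized count scale;
    FDR is Benjamini-Hochberg.
    """
    idx_a = counts.samples_for(group_a)
    idx_b = counts.samples_for(group_b)
    if not idx_a or not idx_b:
        raise ValueError("each group needs at least one sample")
    raw = counts.counts.astype(float)
    size = median_of_ratios_size_factors(raw)
    norm = raw / size
    a = norm[:, idx_a]
    b = norm[:, idx_b]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    all_zero = (raw.sum(axis=1) == 0)

    if method == "moderated_t":
        p = _moderated_t_p(a, b, pseudocount)
    elif method == "binomial":
        p = _pooled_binomial_p(a, b, len(idx_a), len(idx_b))
    else:
        raise ValueError(f"unknown method {method!r}")

    p = np.where(all_zero, 1.0, p)
    log2fc = np.where(all_zero, 0.0, log2fc)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "mean_a": mean_a,
            "mean_b": mean_b,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    return DEResult(table, size, group_a, group_b)


def _moderated_t_p(a: np.ndarray, b: np.ndarray, pseudocount: float) -> np.ndarray:
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    na, nb = la.shape[1], lb.shape[1]
    df_resid = na + nb - 2
    diff = lb.mean(axis=1) - la.mean(axis=1)
    if df_resid <= 0:
        raise ValueError("moderated t needs >= 2 samples in one group")
    rss = ((la - la.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (lb - lb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = rss / df_resid
    abundance = np.concatenate([la, lb], axis=1).mean(axis=1)
    s2_mod, d0 = _moderate_variances(s2, df_resid, abundance)
    df_total = df_resid + d0
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _pooled_binomial_p(
    a: np.ndarray, b: np.ndarray, na: int, nb: int
) -> np.ndarray:
    """Two-sided exact binomial test on pooled normalized counts per gene."""
    ka = np.round(a.sum(axis=1)).astype(np.int64)
    kb = np.round(b.sum(axis=1)).astype(np.int64)
    prob_a = na / (na + nb)
    p = np.ones(len(ka))
    for i, (x, n) in enumerate(zip(ka, ka + kb)):
        if n > 0:
            p[i] = stats.binomtest(int(x), int(n), prob_a).pvalue
    return p


# ---------------------------------------------------------------------------
# Gene-set summaries
# ---------------------------------------------------------------------------


def define_totipotency_genes(
    tlsc_vs_esc: DEResult, fold: float = 2.0, fdr: float = 0.05
) -> Set[str]:
    """Genes significantly upregulated strictly more than ``fold``-fold.

    The reference condition (group A) must be the baseline state (ESC); the
    rule is FDR < 0.05 and fold change > fold, both strict, so an exactly
    2-fold gene is excluded.
    """
    t = tlsc_vs_esc.table
    selected = t[(t["fdr"] < fdr) & (t["log2fc"] > np.log2(fold))]
    return set(selected.index)


def updown_fractions(
    de: DEResult, gene_set: Iterable[str], fdr: float = 0.05
) -> Dict[str, float]:
    """Up/down split among the significantly changed members of a gene set."""
    gene_set = set(gene_set)
    missing = gene_set - set(de.gene_ids)
    if missing:
        raise ValueError(f"genes absent from DE result: {sorted(missing)[:5]}")
    sub = de.table.loc[sorted(gene_set)]
    sig = sub[sub["fdr"] < fdr]
    if len(sig) == 0:
        raise ValueError(
            f"no significant members at FDR<{fdr} "
            f"(set size {len(gene_set)}, 0 significant)"
        )
    n_up = int((sig["log2fc"] > 0).sum())
    n_down = len(sig) - n_up
    return {
        "n_up": n_up,
        "n_down": n_down,
        "frac_up": n_up / len(sig),
        "frac_down": n_down / len(sig),
        "n_significant": len(sig),
    }


def set_overlap_fractions(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> Dict[str, float]:
    """|A∩B|/|A| and companion fractions, with membership checked."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a:
        raise ValueError("empty set A")
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    inter = a & b
    return {
        "frac_a_in_b": len(inter) / len(a),
        "frac_b_in_a": len(inter) / len(b) if b else 0.0,
        "n_intersection": len(inter),
        "n_a": len(a),
        "n_b": len(b),
        "frac_a_not_in_b": 1.0 - len(inter) / len(a),
    }
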