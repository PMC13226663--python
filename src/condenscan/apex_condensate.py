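"""Enrich-score computation and condensate-distance calibration.

The core method quantifies how strongly each genomic window is labeled in a
proximity-labeling (APEX) DNA-seq experiment relative to input, as an enrich
score (ES) in [0, 1]; calibrates physical distance-to-condensate against ES
with a cubic polynomial fitted to imaging (FISH) measurements; and calls a
region "inside the condensate" when its ES exceeds the inflection point of
that cubic — the score beyond which predicted distance stops responding to
further enrichment.

The raw per-window statistic is a depth-normalized log2 ratio,

    r_w = log2((apex_cpm_w + pc) / (input_cpm_w + pc)),

min-max scaled to [0, 1] between robust percentile anchors of r over all
windows. Both the raw ratio and the scaled score are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genomic_io import CoverageTrack, GenomicInterval

__all__ = [
    "EnrichProfile",
    "CalibrationPoint",
    "CalibrationCurve",
    "CondensateCall",
    "REFERENCE_CURVE",
    "compute_enrich_score",
    "region_enrich_score",
    "build_calibration_points",
    "select_probe_regions",
    "fit_calibration",
    "inflection_cutoff",
    "predict_distance",
    "call_condensate_regions",
]


@dataclass
class EnrichProfile:
    """Per-window raw log-ratios and scaled enrich scores for one experiment."""

    window_size: int
    raw: Dict[str, np.ndarray]
    es: Dict[str, np.ndarray]
    scale_anchors: Tuple[float, float]

    def windows(self, chrom: str) -> List[GenomicInterval]:
        n = len(self.es[chrom])
        w = self.window_size
        return [GenomicInterval(chrom, i * w, (i + 1) * w) for i in range(n)]

    def n_windows(self) -> int:
        return int(sum(len(a) for a in self.es.values()))


@dataclass(frozen=True)
class CalibrationPoint:
    """One FISH probe: its region ES and summary of measured distances."""

    probe_id: str
    es: float
    distance: float
    n_cells: int
    distance_sd: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"probe {self.probe_id}: n_cells must be >= 1")
        if self.distance < 0:
            raise ValueError(f"probe {self.probe_id}: negative distance")


@dataclass
class CalibrationCurve:
    """Cubic distance model y(x) = c0 + c1 x + c2 x^2 + c3 x^3.

    ``x`` is the enrich score, ``y`` the distance to the nearest condensate
    (micrometres). ``cutoff``, once derived, is the inflection point used for
    membership calling.
    """

    c0: float
    c1: float
    c2: float
    c3: float
    domain: Tuple[float, float] = (0.0, 1.0)
    residual_sd: float = 0.0
    coef_se: Optional[Tuple[float, float, float, float]] = None
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        for c in (self.c0, self.c1, self.c2, self.c3):
            if not np.isfinite(c):
                raise ValueError("non-finite coefficient")
        if not self.domain[0] < self.domain[1]:
            raise ValueError("domain must satisfy x_min < x_max")

    @property
    def coefficients(self) -> Tuple[float, float, float, float]:
        return (self.c0, self.c1, self.c2, self.c3)

    def __call__(self, es) -> np.ndarray:
        return predict_distance(self, es)


#: Calibration reported for the original RYBP condensate experiment:
#: y = 2.42 - 17.1 x + 45 x^2 - 38.8 x^3 (distance in micrometres vs ES).
REFERENCE_CURVE = CalibrationCurve(2.42, -17.1, 45.0, -38.8)

#: Membership cutoff reported alongside the reference calibration.
REFERENCE_CUTOFF = 0.2924


@dataclass(frozen=True)
class CondensateCall:
    """Membership call for one region: member iff es > cutoff (strict)."""

    region_id: str
    es: float
    member: bool
    cutoff: float
    region: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.member != (self.es > self.cutoff):
            raise ValueError("member flag inconsistent with es/cutoff")


def compute_enrich_score(
    apex: CoverageTrack,
    input_track: CoverageTrack,
    window_size: int = 1000,
    pseudocount: float = 0.5,
    scale_pct: Tuple[float, float] = (1.0, 99.0),
) -> EnrichProfile:
    """Score APEX enrichment over input per genomic window.

    Per window ``w``: ``r_w = log2((apex_cpm_w + pc)/(input_cpm_w + pc))``
    with CPM = window counts per million total; the scaled score is
    ``clip((r_w - q_lo)/(q_hi - q_lo), 0, 1)`` where the anchors are the
    ``scale_pct`` percentiles of r over all windows. CPM normalization makes
    the score invariant to library depth.
    """
    if apex.bin_size != input_track.bin_size:
        raise ValueError("tracks must share a bin grid")
    if window_size % apex.bin_size != 0:
        raise ValueError("window_size must be a multiple of bin_size")
    if set(apex.values) != set(input_track.values):
        raise ValueError("tracks must cover the same chromosomes")
    if apex.total_counts <= 0 or input_track.total_counts <= 0:
        raise ValueError("tracks must have positive total counts")
    bins_per_window = window_size // apex.bin_size

    raw: Dict[str, np.ndarray] = {}
    for chrom in apex.values:
        a = _window_sums(apex.values[chrom], bins_per_window)
        b = _window_sums(input_track.values[chrom], bins_per_window)
        if len(a) != len(b):
            raise ValueError(f"track lengths differ on {chrom}")
        a_cpm = a / apex.total_counts * 1e6
        b_cpm = b / input_track.total_counts * 1e6
        raw[chrom] = np.log2((a_cpm + pseudocount) / (b_cpm + pseudocount))

    pooled = np.concatenate(list(raw.values()))
    q_lo, q_hi = np.percentile(pooled, scale_pct)
    if q_hi == q_lo:
        raise ValueError(
            "non-informative experiment: enrich ratios are degenerate"
        )
    es = {c: np.clip((r - q_lo) / (q_hi - q_lo), 0.0, 1.0) for c, r in raw.items()}
    return EnrichProfile(window_size, raw, es, (float(q_lo), float(q_hi)))


def _window_sums(values: np.ndarray, k: int) -> np.ndarray:
    n = len(values)
    n_windows = -(-n // k)
    padded = np.zeros(n_windows * k)
    padded[:n] = values
    return padded.reshape(n_windows, k).sum(axis=1)


def region_enrich_score(profile: EnrichProfile, region: GenomicInterval) -> float:
    """Length-weighted mean ES over the windows a region overlaps."""
    if region.chrom not in profile.es:
        raise ValueError(f"region chromosome {region.chrom} not in profile")
    es = profile.es[region.chrom]
    w = profile.window_size
    first = region.start // w
    last = (region.end - 1) // w
    if first >= len(es):
        raise ValueError("region does not overlap any scored window")
    last = min(last, len(es) - 1)
    total = 0.0
    weight = 0.0
    for i in range(first, last + 1):
        ov = min(region.end, (i + 1) * w) - max(region.start, i * w)
        total += es[i] * ov
        weight += ov
    if weight == 0:
        raise ValueError("region does not overlap any scored window")
    return total / weight


def build_calibration_points(
    profile: EnrichProfile,
    probes: Mapping[str, GenomicInterval],
    fish: Mapping[str, Sequence[float]],
) -> List[CalibrationPoint]:
    """Pair each FISH probe's region ES with its mean measured distance."""
    points = []
    for probe_id, region in probes.items():
        if probe_id not in fish:
            raise ValueError(f"no FISH distances for probe {probe_id}")
        distances = np.asarray(fish[probe_id], dtype=float)
        if distances.size == 0:
            raise ValueError(f"empty distance list for probe {probe_id}")
        points.append(
            CalibrationPoint(
                probe_id=probe_id,
                es=region_enrich_score(profile, region),
                distance=float(distances.mean()),
                n_cells=int(distances.size),
                distance_sd=float(distances.std(ddof=1))
                if distances.size > 1
                else 0.0,
            )
        )
    missing = set(fish) - set(probes)
    if missing:
        raise ValueError(f"probes without regions: {sorted(missing)}")
    return points


def select_probe_regions(
    profile: EnrichProfile,
    regions: Sequence[GenomicInterval],
    n: int = 12,
) -> List[GenomicInterval]:
    """Choose FISH probe targets spread across the informative score range.

    Regions whose score sits strictly inside (0, 1) — neither floored nor
    saturated by the percentile scaling — are candidates; for each of ``n``
    evenly spaced target scores across the candidates' range, the unused
    candidate with the closest score is chosen. This tiles the assay's
    dynamic range the way FISH probes are designed, without stacking probes
    at the heavily populated score extremes.
    """
    scored = [
        (region_enrich_score(profile, r), r) for r in regions
    ]
    informative = sorted(
        ((s, r) for s, r in scored if 0.0 < s < 1.0), key=lambda t: t[0]
    )
    if len(informative) < n:
        raise ValueError(
            f"only {len(informative)} informative regions for {n} probes"
        )
    scores = np.array([s for s, _ in informative])
    targets = np.linspace(scores[0], scores[-1], n)
    used: set = set()
    chosen = []
    for t in targets:
        order = np.argsort(np.abs(scores - t), kind="stable")
        for i in order:
            if i not in used:
                used.add(int(i))
                chosen.append(informative[i][1])
                break
    return chosen


def fit_calibration(points: Sequence[CalibrationPoint]) -> CalibrationCurve:
    """Ordinary least-squares cubic fit of distance against enrich score."""
    x = np.array([p.es for p in points], dtype=float)
    y = np.array([p.distance for p in points], dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError(
            "rank-deficient calibration: need >= 4 distinct enrich scores"
        )
    X = np.vander(x, 4, increasing=True)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        raise ValueError("rank-deficient calibration design matrix")
    resid = y - X @ beta
    dof = len(x) - 4
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = tuple(float(s) for s in np.sqrt(np.diag(cov)))
    return CalibrationCurve(
        *(float(b) for b in beta),
        domain=(float(x.min()), float(x.max())),
        residual_sd=float(np.sqrt(sigma2)),
        coef_se=se,
    )


def inflection_cutoff(curve: CalibrationCurve) -> float:
    """Inflection point x* of the cubic: the root of y''(x) = 2c2 + 6c3 x.

    x* = -c2 / (3 c3). The value is verified against the second derivative,
    required to lie within the fit domain, and stored on the curve as the
    membership cutoff.
    """
    if curve.c3 == 0:
        raise ValueError("no inflection (degenerate cubic, c3 = 0)")
    x_star = -curve.c2 / (3.0 * curve.c3)
    ypp = 2.0 * curve.c2 + 6.0 * curve.c3 * x_star
    scale = max(abs(curve.c2), abs(curve.c3), 1.0)
    if abs(ypp) >= 1e-9 * scale:
        raise AssertionError("second derivative not zero at closed-form root")
    lo, hi = curve.domain
    if not (lo <= x_star <= hi):
        raise ValueError(
            f"inflection {x_star:.5f} outside fit domain [{lo:.3f}, {hi:.3f}]"
        )
    curve.cutoff = float(x_star)
    return float(x_star)


def predict_distance(curve: CalibrationCurve, es) -> np.ndarray:
    """Evaluate the calibration cubic (Horner form) at one or many scores."""
    x = np.asarray(es, dtype=float)
    lo, hi = curve.domain
    if np.any((x < lo) | (x > hi)):
        warnings.warn(
            "enrich score outside calibration fit domain; extrapolating",
            stacklevel=2,
        )
    result = curve.c0 + x * (curve.c1 + x * (curve.c2 + x * curve.c3))
    return result if result.ndim else float(result)


def call_condensate_regions(
    region_scores: Mapping[str, float] | Sequence[Tuple[GenomicInterval, float]],
    cutoff: Optional[float] = None,
    curve: Optional[CalibrationCurve] = None,
) -> List[CondensateCall]:
    """Call condensate membership: member iff es > cutoff (strictly above).

    ``region_scores`` is either ``{region_id: es}`` or a sequence of
    ``(interval, es)`` pairs. The cutoff may be given directly or taken from a
    calibrated curve.
    """
    if cutoff is None:
        if curve is None or curve.cutoff is None:
            raise ValueError(
                "no cutoff: supply one or a curve with a derived cutoff"
            )
        cutoff = curve.cutoff
    calls = []
    if isinstance(region_scores, Mapping):
        items: Iterable = (
            (rid, es, None) for rid, es in region_scores.items()
        )
    else:
        items = (
            (iv.name or f"{iv.chrom}:{iv.start}-{iv.end}", es, iv)
            for iv, es in region_scores
        )
    for rid, es, iv in items:
        calls.append(
            CondensateCall(
                region_id=rid,
                es=float(es),
                member=bool(es > cutoff),
                cutoff=float(cutoff),
                region=iv,
            )
        )
    return calls


def membership_counts(calls: Sequence[CondensateCall]) -> Dict[str, int]:
    n_member = sum(c.member for c in calls)
    return {
        "n_member": int(n_member),
        "n_non_member": int(len(calls) - n_member),
        "n_total": len(calls),
    }
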