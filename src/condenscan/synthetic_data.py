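"""Seeded generators for every input the pipeline consumes.

Each generator plants a known ground truth (the *blueprint*) so that every
downstream stage — enrich-score recovery, distance calibration, membership
calling, co-occupancy classification, perturbation statistics, puncta
quantification, interactor filtering — can be tested end to end without any
external data. A fixed seed yields byte-identical outputs; ``noiseless=True``
variants return expected values so zero-noise runs are exactly invertible.

The genomic layout emulates a small ESC-like genome: loci of five classes
are placed on a window-aligned grid and carry class-consistent occupancy
marks (RYBP, WDR5, RING1B, STAT3, H3K4me3, H3K27me3, H3K27ac, H2AK119ub1)
plus a planted enrich score ``true_es`` whose image under the truth cubic is
the locus's physical distance to the nearest condensate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genomic_io import (
    CountMatrix,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    PeakSet,
)
from .imaging_coloc import PunctaImage
from .interactome import MsTable

__all__ = [
    "LocusBlueprint",
    "SimulationConfig",
    "MARKS",
    "CLASS_MARKS",
    "MEMBER_CLASSES",
    "make_blueprint",
    "simulate_apex_tracks",
    "simulate_fish",
    "simulate_chip",
    "simulate_perturbed_chip",
    "simulate_counts",
    "simulate_images",
    "simulate_ms_tables",
    "genes_from_blueprint",
    "truth_cubic",
    "truth_inflection",
]

#: ChIP targets the generator lays out per locus class.
MARKS = (
    "RYBP",
    "WDR5",
    "RING1B",
    "STAT3",
    "H3K4me3",
    "H3K27me3",
    "H3K27ac",
    "H2AK119ub1",
)

#: Class-consistent mark tables. RYBP_WDR5 loci are transcriptionally active
#: condensate loci (STAT3-positive, no polycomb marks); RYBP_WDR5_RING1B are
#: bivalent condensate loci carrying the repressive marks; the two non-member
#: RYBP classes mirror active/repressive chromatin outside condensates.
CLASS_MARKS: Dict[str, Dict[str, bool]] = {
    "RYBP_WDR5": dict(
        RYBP=True, WDR5=True, RING1B=False, STAT3=True,
        H3K4me3=True, H3K27me3=False, H3K27ac=True, H2AK119ub1=False,
    ),
    "RYBP_WDR5_RING1B": dict(
        RYBP=True, WDR5=True, RING1B=True, STAT3=False,
        H3K4me3=True, H3K27me3=True, H3K27ac=False, H2AK119ub1=True,
    ),
    "RYBP_active_no_WDR5": dict(
        RYBP=True, WDR5=False, RING1B=False, STAT3=True,
        H3K4me3=True, H3K27me3=False, H3K27ac=True, H2AK119ub1=False,
    ),
    "RYBP_repressive": dict(
        RYBP=True, WDR5=False, RING1B=True, STAT3=False,
        H3K4me3=False, H3K27me3=True, H3K27ac=False, H2AK119ub1=True,
    ),
    "background": dict.fromkeys(MARKS, False),
}

#: Classes planted inside condensates (true_es above the truth inflection).
MEMBER_CLASSES = frozenset({"RYBP_WDR5", "RYBP_WDR5_RING1B"})

_DEFAULT_N_LOCI = {
    "RYBP_WDR5": 40,
    "RYBP_WDR5_RING1B": 40,
    "RYBP_active_no_WDR5": 20,
    "RYBP_repressive": 20,
    "background": 60,
}

#: Planted enrich-score ranges per class. Member classes sit above the truth
#: inflection (0.3866 for the default coefficients) with margin while keeping
#: the truth cubic non-negative; non-member classes sit below with margin.
_DEFAULT_ES_RANGES = {
    "RYBP_WDR5": (0.41, 0.56),
    "RYBP_WDR5_RING1B": (0.41, 0.56),
    "RYBP_active_no_WDR5": (0.05, 0.36),
    "RYBP_repressive": (0.05, 0.36),
    "background": (0.0, 0.0),
}


@dataclass(frozen=True)
class LocusBlueprint:
    """Ground truth for one planted locus."""

    locus_id: str
    interval: GenomicInterval
    class_label: str
    true_es: float
    true_distance: float
    marks: Dict[str, bool]
    expression_level: float
    fold_change_on_ko: float

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_MARKS:
            raise ValueError(f"unknown class {self.class_label!r}")
        if not 0.0 <= self.true_es <= 1.0:
            raise ValueError("true_es must be in [0, 1]")
        if self.true_distance < 0:
            raise ValueError("true_distance must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator suite; a fixed seed fixes every output."""

    seed: int = 0
    genome: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000}
    )
    n_loci: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_N_LOCI))
    es_ranges: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_ES_RANGES)
    )
    locus_size: int = 2000
    bin_size: int = 10
    window_size: int = 1000
    depth: float = 2e7
    log2_dynamic_range: float = 3.0  # raw log2 ratio span between es 0 and 1
    pseudocount: float = 0.5  # must match the scorer's default
    # truth calibration: distance(es) = c0 + c1 es + c2 es^2 + c3 es^3
    truth_coefficients: Tuple[float, float, float, float] = (
        2.42,
        -17.1,
        45.0,
        -38.8,
    )
    fish_sd: float = 0.1
    fish_n_cells: int = 50
    # expression / differential expression
    n_replicates: int = 3
    dispersion: float = 0.05
    mean_expression: float = 100.0
    # imaging
    image_shape: Tuple[int, int] = (256, 256)
    pixel_size: float = 0.1
    spot_sigma_px: float = 2.0
    spot_peak: float = 100.0
    image_background: float = 2.0
    image_noise_sd: float = 1.0

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([self.seed, stream])


def truth_cubic(config: SimulationConfig, es) -> np.ndarray:
    c0, c1, c2, c3 = config.truth_coefficients
    x = np.asarray(es, dtype=float)
    y = c0 + x * (c1 + x * (c2 + x * c3))
    return y if y.ndim else float(y)


def truth_inflection(config: SimulationConfig) -> float:
    c0, c1, c2, c3 = config.truth_coefficients
    if c3 == 0:
        raise ValueError("degenerate truth cubic")
    return -c2 / (3.0 * c3)


# ---------------------------------------------------------------------------
# Blueprint
# ---------------------------------------------------------------------------


def make_blueprint(config: SimulationConfig) -> List[LocusBlueprint]:
    """Place non-overlapping, window-aligned loci and assign ground truth.

    Loci are placed uniformly at random on the window grid with at least one
    empty window between neighbours; each receives a class-consistent mark
    table, a ``true_es`` drawn from its class range, and
    ``true_distance = max(truth_cubic(true_es), 0)``.
    """
    rng = config.rng(1)
    w = config.window_size
    if config.locus_size % w != 0:
        raise ValueError("locus_size must be a multiple of window_size")
    windows_per_locus = config.locus_size // w
    classes = [c for c in CLASS_MARKS if config.n_loci.get(c, 0) > 0]
    n_total = sum(config.n_loci.get(c, 0) for c in classes)
    if any(v < 0 for v in config.n_loci.values()):
        raise ValueError("locus counts must be >= 0")

    # candidate slots: window-grid positions per chromosome, 1-window gap
    slot_span = windows_per_locus + 1
    slots: List[Tuple[str, int]] = []
    for chrom, size in config.genome.items():
        n_slots = size // (slot_span * w)
        slots.extend((chrom, i * slot_span * w) for i in range(n_slots))
    if n_total > len(slots):
        raise ValueError(
            f"genome too small: {n_total} loci requested, {len(slots)} slots"
        )
    chosen = rng.choice(len(slots), size=n_total, replace=False)
    chosen = sorted(chosen)

    labels: List[str] = []
    for c in classes:
        labels.extend([c] * config.n_loci[c])
    rng.shuffle(labels)

    out: List[LocusBlueprint] = []
    for i, (slot_idx, label) in enumerate(zip(chosen, labels)):
        chrom, start = slots[slot_idx]
        lo, hi = config.es_ranges.get(label, (0.0, 0.0))
        es = float(lo if lo == hi else rng.uniform(lo, hi))
        expr = float(rng.lognormal(np.log(config.mean_expression), 0.5))
        if label == "RYBP_WDR5":
            fold = 0.25  # active condensate genes drop on depletion
        elif label == "RYBP_WDR5_RING1B":
            fold = 4.0  # repressed condensate genes derepress
        else:
            fold = 1.0
        out.append(
            LocusBlueprint(
                locus_id=f"locus_{i:04d}",
                interval=GenomicInterval(
                    chrom, start, start + config.locus_size, name=f"locus_{i:04d}"
                ),
                class_label=label,
                true_es=es,
                true_distance=float(max(truth_cubic(config, es), 0.0)),
                marks=dict(CLASS_MARKS[label]),
                expression_level=expr,
                fold_change_on_ko=fold,
            )
        )
    return out


# ---------------------------------------------------------------------------
# APEX tracks
# ---------------------------------------------------------------------------


def _window_es_layout(
    blueprint: Sequence[LocusBlueprint], config: SimulationConfig
) -> Dict[str, np.ndarray]:
    """Per-window true enrich score (0 outside loci)."""
    w = config.window_size
    layout = {
        chrom: np.zeros(math.ceil(size / w))
        for chrom, size in config.genome.items()
    }
    for locus in blueprint:
        iv = locus.interval
        first, last = iv.start // w, (iv.end - 1) // w
        layout[iv.chrom][first : last + 1] = locus.true_es
    return layout


def _expected_window_cpm(
    blueprint: Sequence[LocusBlueprint], config: SimulationConfig
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Expected APEX and input CPM per window.

    The input is flat. APEX CPM is chosen so the scorer's raw statistic
    ``log2((apex_cpm + pc)/(input_cpm + pc))`` equals ``r0 + s * true_es``
    exactly — affine in the planted score — with the offset ``r0`` solved
    numerically so that APEX CPMs total 1e6 (the self-consistency
    calibration: in the noiseless limit the recovered score is an affine,
    hence order- and inflection-preserving, image of the truth).
    """
    layout = _window_es_layout(blueprint, config)
    es_all = np.concatenate([v for v in layout.values()])
    n_windows = es_all.size
    input_cpm = 1e6 / n_windows
    pc = config.pseudocount
    s = config.log2_dynamic_range

    def total(r0: float) -> float:
        return float(
            ((input_cpm + pc) * np.exp2(r0 + s * es_all) - pc).sum() - 1e6
        )

    r0 = brentq(total, -30.0, 30.0, xtol=1e-12, rtol=1e-14)
    apex = {
        chrom: (input_cpm + pc) * np.exp2(r0 + s * es) - pc
        for chrom, es in layout.items()
    }
    if any(np.any(v < 0) for v in apex.values()):
        raise ValueError(
            "infeasible APEX layout: negative expected coverage; reduce "
            "log2_dynamic_range or pseudocount"
        )
    inp = {chrom: np.full_like(es, input_cpm) for chrom, es in layout.items()}
    return apex, inp


def simulate_apex_tracks(
    blueprint: Sequence[LocusBlueprint],
    config: SimulationConfig,
    noiseless: bool = False,
) -> Tuple[CoverageTrack, CoverageTrack]:
    """Paired APEX-labeled and input coverage tracks at the configured depth.

    Counts are Poisson around the expected per-bin rate (``noiseless=True``
    returns the expectations themselves). Bin-level tracks carry uniform
    signal within each scoring window.
    """
    if config.depth <= 0:
        raise ValueError("sequencing depth must be positive")
    apex_cpm, input_cpm = _expected_window_cpm(blueprint, config)
    bins_per_window = config.window_size // config.bin_size
    rng = config.rng(2)
    tracks = []
    for cpm in (apex_cpm, input_cpm):
        values: Dict[str, np.ndarray] = {}
        for chrom, size in config.genome.items():
            n_bins = math.ceil(size / config.bin_size)
            per_window_counts = cpm[chrom] * config.depth / 1e6
            per_bin = np.repeat(
                per_window_counts / bins_per_window, bins_per_window
            )[:n_bins]
            if not noiseless:
                per_bin = rng.poisson(per_bin).astype(float)
            values[chrom] = per_bin
        total = float(sum(v.sum() for v in values.values()))
        tracks.append(CoverageTrack(config.bin_size, values, total))
    return tracks[0], tracks[1]


# ---------------------------------------------------------------------------
# FISH distances
# ---------------------------------------------------------------------------


def simulate_fish(
    probes: Mapping[str, float] | Sequence[LocusBlueprint],
    config: SimulationConfig,
    sd: Optional[float] = None,
    n_cells: Optional[int] = None,
) -> Dict[str, List[float]]:
    """Per-probe distance measurements around the truth cubic.

    ``probes`` is either ``{probe_id: true_es}`` or a list of blueprint loci
    (probed at their planted scores). Each probe yields ``n_cells`` draws of
    ``max(0, Normal(truth_cubic(es), sd))`` — distances cannot be negative.
    """
    sd = config.fish_sd if sd is None else sd
    n_cells = config.fish_n_cells if n_cells is None else n_cells
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not isinstance(probes, Mapping):
        probes = {locus.locus_id: locus.true_es for locus in probes}
    rng = config.rng(3)
    out: Dict[str, List[float]] = {}
    for probe_id, es in probes.items():
        mu = truth_cubic(config, es)
        draws = np.maximum(0.0, rng.normal(mu, sd, size=n_cells))
        out[probe_id] = [float(x) for x in draws]
    return out


# ---------------------------------------------------------------------------
# ChIP peaks and tracks
# ---------------------------------------------------------------------------


def simulate_chip(
    blueprint: Sequence[LocusBlueprint],
    config: SimulationConfig,
    noiseless: bool = False,
    enrichment: float = 8.0,
    background: float = 1.0,
) -> Tuple[Dict[str, PeakSet], Dict[str, CoverageTrack]]:
    """Peak sets and coverage tracks for every ChIP target.

    Each mark produces a peak exactly over every locus where the blueprint
    sets it true, and a track with ``background + enrichment`` expected
    signal inside those loci (``background`` elsewhere), Poisson-sampled
    unless ``noiseless``.
    """
    rng = config.rng(4)
    peaks: Dict[str, PeakSet] = {}
    tracks: Dict[str, CoverageTrack] = {}
    for mark in MARKS:
        marked = [loc for loc in blueprint if loc.marks[mark]]
        peaks[mark] = PeakSet([loc.interval for loc in marked], source_label=mark)
        values: Dict[str, np.ndarray] = {}
        for chrom, size in config.genome.items():
            n_bins = math.ceil(size / config.bin_size)
            expected = np.full(n_bins, background)
            for loc in marked:
                if loc.interval.chrom != chrom:
                    continue
                b0 = loc.interval.start // config.bin_size
                b1 = (loc.interval.end - 1) // config.bin_size
                expected[b0 : b1 + 1] = background + enrichment
            values[chrom] = (
                expected if noiseless else rng.poisson(expected).astype(float)
            )
        total = float(sum(v.sum() for v in values.values()))
        tracks[mark] = CoverageTrack(config.bin_size, values, total)
    return peaks, tracks


def simulate_perturbed_chip(
    blueprint: Sequence[LocusBlueprint],
    config: SimulationConfig,
    mark: str = "RING1B",
    decrease_fraction: float = 0.77,
    scale: float = 0.3,
    noiseless: bool = True,
    enrichment: float = 8.0,
    background: float = 1.0,
) -> Tuple[CoverageTrack, CoverageTrack, List[str]]:
    """Before/after tracks where a stated fraction of marked loci lose signal.

    Exactly ``round(decrease_fraction * n)`` of the loci carrying ``mark``
    have their enrichment scaled by ``scale`` in the after track; all other
    signal is untouched. Returns (before, after, affected locus ids).
    """
    if not 0.0 <= decrease_fraction <= 1.0:
        raise ValueError("decrease_fraction must be in [0, 1]")
    rng = config.rng(5)
    marked = [loc for loc in blueprint if loc.marks[mark]]
    n_affected = round(decrease_fraction * len(marked))
    affected_idx = rng.choice(len(marked), size=n_affected, replace=False)
    affected = {marked[i].locus_id for i in affected_idx}

    def build(perturbed: bool) -> CoverageTrack:
        values: Dict[str, np.ndarray] = {}
        for chrom, size in config.genome.items():
            n_bins = math.ceil(size / config.bin_size)
            expected = np.full(n_bins, background)
            for loc in marked:
                if loc.interval.chrom != chrom:
                    continue
                gain = enrichment
                if perturbed and loc.locus_id in affected:
                    gain = enrichment * scale
                b0 = loc.interval.start // config.bin_size
                b1 = (loc.interval.end - 1) // config.bin_size
                expected[b0 : b1 + 1] = background + gain
            values[chrom] = (
                expected if noiseless else rng.poisson(expected).astype(float)
            )
        total = float(sum(v.sum() for v in values.values()))
        return CoverageTrack(config.bin_size, values, total)

    return build(False), build(True), sorted(affected)


# ---------------------------------------------------------------------------
# RNA counts
# ---------------------------------------------------------------------------


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    blueprint: Sequence[LocusBlueprint],
    config: SimulationConfig,
    libsize_factors: Optional[Sequence[float]] = None,
    condition_a: str = "WT",
    condition_b: str = "KO",
) -> CountMatrix:
    """Two-condition RNA count matrix with planted fold changes.

    One gene per locus; condition A means are the blueprint expression
    levels, condition B means are scaled by ``fold_change_on_ko``. Counts
    are negative binomial with the configured dispersion; optional
    per-sample library-size factors multiply the means.
    """
    if config.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = config.rng(6)
    n_rep = config.n_replicates
    if libsize_factors is None:
        libsize_factors = [1.0] * (2 * n_rep)
    if len(libsize_factors) != 2 * n_rep:
        raise ValueError("one library-size factor per sample required")
    gene_ids = [loc.locus_id for loc in blueprint]
    base = np.array([loc.expression_level for loc in blueprint])
    fold = np.array([loc.fold_change_on_ko for loc in blueprint])
    cols = []
    for s in range(2 * n_rep):
        mu = base * (fold[:] if s >= n_rep else 1.0) * libsize_factors[s]
        cols.append(_nb_draw(rng, mu, config.dispersion))
    counts = np.stack(cols, axis=1)
    sample_ids = [f"{condition_a}_{i+1}" for i in range(n_rep)] + [
        f"{condition_b}_{i+1}" for i in range(n_rep)
    ]
    labels = [condition_a] * n_rep + [condition_b] * n_rep
    return CountMatrix(gene_ids, sample_ids, counts, condition_labels=labels)


def genes_from_blueprint(
    blueprint: Sequence[LocusBlueprint], config: SimulationConfig
) -> List[GeneModel]:
    """One gene per locus with the TSS at the locus start (plus strand)."""
    return [
        GeneModel(
            gene_id=loc.locus_id,
            chrom=loc.interval.chrom,
            strand="+",
            tss=loc.interval.start,
            body=loc.interval,
        )
        for loc in blueprint
    ]


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def simulate_images(
    config: SimulationConfig,
    channels: Sequence[str] = ("RYBP", "WDR5", "RING1B"),
    n_puncta: int = 40,
    coloc_fractions: Optional[Mapping[str, float]] = None,
    min_separation_px: float = 10.0,
) -> Tuple[PunctaImage, pd.DataFrame]:
    """Multi-channel image of Gaussian puncta with a planted truth table.

    Puncta positions are drawn for the first (reference) channel with a
    minimum pairwise separation; each subsequent channel is present at a
    punctum with its configured ``coloc_fraction`` (default 0.5). Returns
    the image plus a table of planted centroids and channel memberships.
    """
    rng = config.rng(7)
    h, w = config.image_shape
    sigma = config.spot_sigma_px
    margin = 4 * sigma
    if coloc_fractions is None:
        coloc_fractions = {ch: 0.5 for ch in channels[1:]}

    positions: List[Tuple[float, float]] = []
    attempts = 0
    while len(positions) < n_puncta:
        attempts += 1
        if attempts > 200 * n_puncta:
            raise ValueError(
                "puncta density too high to place without overlap"
            )
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all(
            (y - py) ** 2 + (x - px) ** 2 >= min_separation_px**2
            for py, px in positions
        ):
            positions.append((y, x))

    membership = {channels[0]: np.ones(n_puncta, dtype=bool)}
    for ch in channels[1:]:
        frac = coloc_fractions.get(ch, 0.5)
        membership[ch] = rng.random(n_puncta) < frac

    yy, xx = np.mgrid[0:h, 0:w]
    images: Dict[str, np.ndarray] = {}
    for ch in channels:
        img = np.full((h, w), config.image_background, dtype=float)
        for (py, px), present in zip(positions, membership[ch]):
            if not present:
                continue
            img += config.spot_peak * np.exp(
                -((yy - py) ** 2 + (xx - px) ** 2) / (2 * sigma**2)
            )
        if config.image_noise_sd > 0:
            img = img + rng.normal(0.0, config.image_noise_sd, size=(h, w))
        images[ch] = np.clip(img, 0.0, None)

    truth = pd.DataFrame(
        {
            "punctum": range(n_puncta),
            "y_px": [p[0] for p in positions],
            "x_px": [p[1] for p in positions],
            **{f"in_{ch}": membership[ch] for ch in channels},
        }
    )
    return PunctaImage(images, pixel_size=config.pixel_size), truth


# ---------------------------------------------------------------------------
# Mass-spectrometry tables
# ---------------------------------------------------------------------------


def simulate_ms_tables(
    config: SimulationConfig,
    n_partners: int = 20,
    n_decoys: int = 80,
    bait: str = "RING1B",
) -> Dict[str, object]:
    """IP-MS peptide-count and SILAC intensity tables with planted partners.

    Planted partners receive measurements comfortably above the calling
    thresholds (strict >2 peptides and >1.5x control); decoys receive
    measurements that fail at least one rule. Returns the four tables keyed
    ``ip``, ``control``, ``light`` (bait) and ``heavy`` (tag-only control).
    """
    rng = config.rng(8)
    partners = [f"PARTNER_{i:03d}" for i in range(n_partners)]
    decoys = [f"DECOY_{i:03d}" for i in range(n_decoys)]

    ip: Dict[str, float] = {}
    ctrl: Dict[str, float] = {}
    light: Dict[str, float] = {}
    heavy: Dict[str, float] = {}
    for p in partners:
        peptides = int(rng.integers(5, 30))
        ip[p] = peptides
        ctrl[p] = int(rng.integers(0, max(1, peptides // 3)))
        heavy_i = float(rng.uniform(1.0, 5.0))
        heavy[p] = heavy_i
        light[p] = heavy_i * float(rng.uniform(2.0, 10.0))
    for d in decoys:
        mode = rng.integers(0, 3)
        if mode == 0:  # too few peptides (<= 2: "exceeds two" is strict)
            ip[d] = int(rng.integers(0, 3))
            ctrl[d] = int(rng.integers(0, 2))
        elif mode == 1:  # enough peptides but not above 1.5x control
            peptides = int(rng.integers(3, 10))
            ip[d] = peptides
            ctrl[d] = int(math.ceil(peptides / 1.5))
        else:  # background in both
            ip[d] = int(rng.integers(0, 2))
            ctrl[d] = int(rng.integers(2, 6))
        heavy_i = float(rng.uniform(2.0, 6.0))
        heavy[d] = heavy_i
        light[d] = heavy_i * float(rng.uniform(0.2, 1.5))
    return {
        "ip": MsTable(ip, bait=bait, assay_kind="peptide_count"),
        "control": MsTable(ctrl, bait="BirA", assay_kind="peptide_count"),
        "light": MsTable(light, bait="WDR5", assay_kind="silac_intensity"),
        "heavy": MsTable(heavy, bait="GFP", assay_kind="silac_intensity"),
        "planted": partners,
    }
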