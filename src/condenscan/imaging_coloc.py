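"""Puncta detection and co-localization quantification.

Quantifies nuclear condensates ("puncta") in multi-channel fluorescence
images: threshold-based spot segmentation, greedy centroid pairing across
channels, per-punctum channel-enrichment calls ("positive fraction"),
thresholded Manders overlap coefficients, per-cell focus counts, and
point-to-nearest-punctum distances (the measurement feeding the FISH
distance calibration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "PunctaImage",
    "Punctum",
    "PunctaSet",
    "ColocResult",
    "detect_puncta",
    "coloc_puncta",
    "puncta_positive_fraction",
    "manders_coefficients",
    "nearest_puncta_distance",
    "foci_count_per_cell",
]


@dataclass
class PunctaImage:
    """Named non-negative channel arrays sharing one pixel grid.

    ``pixel_size`` is the physical size of one pixel per axis (micrometres);
    a scalar means isotropic pixels.
    """

    channels: Dict[str, np.ndarray]
    pixel_size: float | Tuple[float, ...] = 1.0

    def __post_init__(self) -> None:
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        for name, arr in self.channels.items():
            if np.any(arr < 0):
                raise ValueError(f"negative intensities in channel {name}")
        ps = np.atleast_1d(np.asarray(self.pixel_size, dtype=float))
        if np.any(ps <= 0):
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> Tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def pixel_size_vector(self) -> np.ndarray:
        ps = np.atleast_1d(np.asarray(self.pixel_size, dtype=float))
        if ps.size == 1:
            ps = np.full(len(self.shape), ps[0])
        if ps.size != len(self.shape):
            raise ValueError("pixel_size length must match image dimensions")
        return ps


@dataclass
class Punctum:
    """One detected spot: mask label, physical centroid, per-channel means."""

    punctum_id: int
    centroid: Tuple[float, ...]  # physical units
    centroid_px: Tuple[float, ...]
    area: int
    channel_means: Dict[str, float]


class PunctaSet:
    """Detected puncta plus the labeled mask they came from."""

    def __init__(
        self,
        puncta: Sequence[Punctum],
        labels: np.ndarray,
        channel: str,
        pixel_size: np.ndarray,
    ) -> None:
        self.puncta = list(puncta)
        self.labels = labels
        self.channel = channel
        self.pixel_size = pixel_size

    def __len__(self) -> int:
        return len(self.puncta)

    def __iter__(self):
        return iter(self.puncta)

    def centroids(self, physical: bool = True) -> np.ndarray:
        if not self.puncta:
            return np.empty((0, self.labels.ndim))
        key = "centroid" if physical else "centroid_px"
        return np.array([getattr(p, key) for p in self.puncta])

    def mask_of(self, punctum: Punctum) -> np.ndarray:
        return self.labels == punctum.punctum_id


@dataclass(frozen=True)
class ColocResult:
    """Thresholded Manders coefficients for a channel pair."""

    m1: float
    m2: float
    threshold_a: float
    threshold_b: float
    n_above_a: int
    n_above_b: int


def _threshold(img: np.ndarray, method: str, k: float) -> float:
    if method == "otsu":
        if img.max() == img.min():
            raise ValueError("constant image: Otsu threshold undefined")
        return float(threshold_otsu(img))
    if method == "mean_plus_k_sd":
        return float(img.mean() + k * img.std())
    raise ValueError(f"unknown threshold method {method!r}")


def detect_puncta(
    image: PunctaImage,
    channel: str,
    method: str = "otsu",
    k: float = 3.0,
    min_area: int = 4,
    mask: Optional[np.ndarray] = None,
) -> PunctaSet:
    """Segment puncta in one channel.

    Threshold (Otsu or mean + k*sd) -> binary mask -> 8-connected
    components -> components of at least ``min_area`` pixels become puncta
    with intensity-weighted centroids. An empty result is not an error.
    ``mask`` restricts both thresholding statistics and detection to a
    region (used for per-cell counting).
    """
    if channel not in image.channels:
        raise KeyError(f"no channel {channel!r}")
    img = image.channels[channel].astype(float)
    if mask is not None:
        stats_pixels = img[mask]
        if stats_pixels.size == 0:
            raise ValueError("empty mask")
        if method == "otsu" and stats_pixels.max() == stats_pixels.min():
            raise ValueError("constant image: Otsu threshold undefined")
        thr = (
            float(threshold_otsu(stats_pixels))
            if method == "otsu"
            else float(stats_pixels.mean() + k * stats_pixels.std())
        )
        binary = (img > thr) & mask
    else:
        thr = _threshold(img, method, k)
        binary = img > thr
    labels = cc_label(binary, connectivity=img.ndim)  # full connectivity (8 in 2D)
    ps = image.pixel_size_vector()
    puncta: List[Punctum] = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for prop in regionprops(labels, intensity_image=img):
        if prop.area < min_area:
            continue
        keep[prop.label] = True
        centroid_px = tuple(float(c) for c in prop.centroid_weighted)
        centroid = tuple(float(c * s) for c, s in zip(centroid_px, ps))
        region_mask = labels == prop.label
        means = {
            name: float(arr[region_mask].mean())
            for name, arr in image.channels.items()
        }
        puncta.append(
            Punctum(
                punctum_id=prop.label,
                centroid=centroid,
                centroid_px=centroid_px,
                area=int(prop.area),
                channel_means=means,
            )
        )
    labels[~keep[labels]] = 0
    return PunctaSet(puncta, labels, channel, ps)


def coloc_puncta(
    a: PunctaSet, b: PunctaSet, max_centroid_dist: float = 0.3
) -> List[Tuple[Punctum, Punctum, float]]:
    """Greedy nearest-neighbour pairing of puncta under a distance cap.

    Candidate pairs within ``max_centroid_dist`` (physical units) are taken
    in order of increasing distance; each punctum is used at most once.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    ca, cb = a.centroids(), b.centroids()
    diff = ca[:, None, :] - cb[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    candidates = [
        (dist[i, j], i, j)
        for i in range(len(a))
        for j in range(len(b))
        if dist[i, j] <= max_centroid_dist
    ]
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a, used_b = set(), set()
    pairs = []
    for d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((a.puncta[i], b.puncta[j], float(d)))
    return pairs


def puncta_positive_fraction(
    puncta: PunctaSet,
    image: PunctaImage,
    channel: str,
    enrich_ratio: float = 2.0,
) -> Tuple[float, List[bool]]:
    """Fraction of puncta visibly enriched for another channel.

    A punctum is positive when its mean intensity in ``channel`` (within the
    punctum mask) strictly exceeds ``enrich_ratio`` times the channel's
    whole-frame median — an operational stand-in for "obvious" enrichment.
    """
    if len(puncta) == 0:
        raise ValueError("empty puncta set")
    if channel not in image.channels:
        raise KeyError(f"no channel {channel!r}")
    ref = float(np.median(image.channels[channel]))
    flags = [
        p.channel_means[channel] > enrich_ratio * ref for p in puncta
    ]
    return sum(flags) / len(flags), flags


def manders_coefficients(
    image: PunctaImage,
    channel_a: str,
    channel_b: str,
    thresholds: Optional[Tuple[float, float]] = None,
) -> ColocResult:
    """Thresholded Manders overlap coefficients for two channels.

    M1 is the fraction of channel-A intensity (over pixels with A above its
    threshold) that falls on pixels where B is above its threshold; M2 is
    the symmetric quantity. Thresholds default to per-channel Otsu.
    """
    a = image.channels[channel_a].astype(float)
    b = image.channels[channel_b].astype(float)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("zero total intensity in a channel")
    if thresholds is None:
        t_a, t_b = _threshold(a, "otsu", 0), _threshold(b, "otsu", 0)
    else:
        t_a, t_b = thresholds
    above_a = a > t_a
    above_b = b > t_b
    denom1 = a[above_a].sum()
    denom2 = b[above_b].sum()
    if denom1 == 0 or denom2 == 0:
        raise ValueError("no pixels above threshold in a channel")
    m1 = a[above_a & above_b].sum() / denom1
    m2 = b[above_a & above_b].sum() / denom2
    return ColocResult(
        m1=float(m1),
        m2=float(m2),
        threshold_a=float(t_a),
        threshold_b=float(t_b),
        n_above_a=int(above_a.sum()),
        n_above_b=int(above_b.sum()),
    )


def nearest_puncta_distance(
    points: np.ndarray, puncta: PunctaSet
) -> np.ndarray:
    """Euclidean distance (physical units) from each point to the nearest
    punctum centroid.

    ``points`` are physical coordinates, shape (n, ndim); anisotropic pixel
    sizes are already folded into the centroids.
    """
    if len(puncta) == 0:
        raise ValueError("no reference puncta")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(puncta.centroids())
    dist, _ = tree.query(points)
    return np.asarray(dist, dtype=float)


def foci_count_per_cell(
    image: PunctaImage,
    foci_channel: str,
    cell_masks: Sequence[np.ndarray],
    method: str = "mean_plus_k_sd",
    k: float = 3.0,
    min_area: int = 4,
) -> Dict[str, object]:
    """Count detected foci within each cell mask.

    Masks must be pairwise disjoint. Returns per-cell counts plus the
    mean +/- SEM summary used for condition comparisons.
    """
    if not cell_masks:
        raise ValueError("no cell masks provided")
    combined = np.zeros(image.shape, dtype=int)
    for m in cell_masks:
        combined += m.astype(int)
    if combined.max() > 1:
        raise ValueError("cell masks overlap")
    counts = []
    for m in cell_masks:
        if not m.any():
            raise ValueError("empty cell mask")
        detected = detect_puncta(
            image, foci_channel, method=method, k=k, min_area=min_area, mask=m
        )
        counts.append(len(detected))
    counts_arr = np.array(counts, dtype=float)
    sem = (
        counts_arr.std(ddof=1) / np.sqrt(len(counts_arr))
        if len(counts_arr) > 1
        else 0.0
    )
    return {
        "counts": counts,
        "mean": float(counts_arr.mean()),
        "sem": float(sem),
        "n_cells": len(counts),
    }
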