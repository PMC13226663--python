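import numpy as np
import pytest

from condenscan.synthetic_data import SimulationConfig, make_blueprint


@pytest.fixture(scope="session")
def small_config():
    """A small genome with one locus per class: fast, deterministic."""
    return SimulationConfig(
        seed=0,
        genome={"chr1": 200_000},
        n_loci={
            "RYBP_WDR5": 1,
            "RYBP_WDR5_RING1B": 1,
            "RYBP_active_no_WDR5": 1,
            "RYBP_repressive": 1,
            "background": 1,
        },
    )


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def default_blueprint(default_config):
    return make_blueprint(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_intervals(rng, n, chrom_len=100_000, chroms=("chr1", "chr2")):
    """n random raw intervals (possibly overlapping) for oracle tests."""
    from condenscan.genomic_io import GenomicInterval

    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_len - 200))
        length = int(rng.integers(1, 200))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def occupancy_mask(intervals, chrom_len, chroms):
    """Per-base boolean occupancy — the brute-force oracle representation."""
    masks = {c: np.zeros(chrom_len, dtype=bool) for c in chroms}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def mask_to_intervals(masks):
    from condenscan.genomic_io import GenomicInterval

    out = []
    for chrom in sorted(masks):
        m = masks[chrom]
        padded = np.concatenate([[False], m, [False]])
        diff = np.diff(padded.astype(int))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out
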