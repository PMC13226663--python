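"""Call protein interactors from IP-MS and SILAC tables.

Simulates pull-down tables with planted partners, applies the strict
peptide-count and intensity-ratio filters, intersects the two partner sets,
and ranks the shared partners by intrinsically-disordered-region content.
"""

import numpy as np

from condenscan.interactome import (
    call_partners_by_intensity,
    call_partners_by_peptides,
    idr_fraction_summary,
    shared_partners,
)
from condenscan.synthetic_data import SimulationConfig, simulate_ms_tables

config = SimulationConfig(seed=0)
tables = simulate_ms_tables(config, n_partners=20, n_decoys=80)

peptide_partners = call_partners_by_peptides(
    tables["ip"], tables["control"], min_peptides=2, ratio=1.5
)
silac_partners = call_partners_by_intensity(
    tables["light"], tables["heavy"], ratio=1.5
)
print(f"peptide-count filter: {len(peptide_partners)} partners "
      f"(> 2 peptides and > 1.5x control)")
print(f"SILAC filter: {len(silac_partners)} partners (> 1.5x control)")

shared = shared_partners(peptide_partners, silac_partners)
print(f"shared partners of the two baits: {len(shared)}")
# Shared partners of an activating and a repressive bait are candidate
# regulators of selective genomic binding.

rng = np.random.default_rng(0)
annotation = {
    p: list(rng.random(rng.integers(200, 600)) < rng.uniform(0.1, 0.9))
    for p in shared
}
ranking = idr_fraction_summary(sorted(shared), annotation)
top = ranking.index[0]
print(f"highest-IDR shared partner: {top} "
      f"({ranking.loc[top, 'idr_fraction']:.0%} disordered residues)")
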