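"""Interactor calling from IP-MS peptide counts and SILAC intensities.

The filters are the published ones for pull-down proteomics against a tag-only
control: for peptide-count IP-MS a protein is a partner when its peptide
count strictly exceeds 2 and strictly exceeds 1.5x the control count; for
SILAC intensities, when its intensity strictly exceeds 1.5x the control.
Proteins absent from the control are treated as control = 0 (the most
permissive reading; the protocols do not address missing controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Set

import pandas as pd

__all__ = [
    "MsTable",
    "PartnerSet",
    "call_partners_by_peptides",
    "call_partners_by_intensity",
    "shared_partners",
    "idr_fraction_summary",
]


@dataclass
class MsTable:
    """Protein -> measurement for one pull-down experiment."""

    measurements: Dict[str, float]
    bait: str
    assay_kind: str  # "peptide_count" or "silac_intensity"

    def __post_init__(self) -> None:
        if self.assay_kind not in ("peptide_count", "silac_intensity"):
            raise ValueError(f"unknown assay kind {self.assay_kind!r}")
        for protein, value in self.measurements.items():
            if value < 0:
                raise ValueError(f"negative measurement for {protein}")
            if self.assay_kind == "peptide_count" and value != int(value):
                raise ValueError(
                    f"peptide count for {protein} must be an integer"
                )

    def get(self, protein: str) -> float:
        return self.measurements.get(protein, 0.0)

    @classmethod
    def from_tsv(cls, path, bait: str, assay_kind: str) -> "MsTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))),
            bait=bait,
            assay_kind=assay_kind,
        )


@dataclass
class PartnerSet:
    """Proteins passing the calling rule, with their ratios vs control."""

    bait: str
    proteins: Set[str]
    ratios: Dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, protein: str) -> bool:
        return protein in self.proteins


def _ratio(value: float, control: float) -> float:
    return value / control if control > 0 else float("inf")


def call_partners_by_peptides(
    ip: MsTable,
    control: MsTable,
    min_peptides: int = 2,
    ratio: float = 1.5,
) -> PartnerSet:
    """Partner iff peptides > min_peptides and peptides > ratio * control.

    Both thresholds are strict ("exceeds two", "greater than 1.5 times"), so
    a protein with exactly 2 peptides is excluded.
    """
    if ip.assay_kind != "peptide_count" or control.assay_kind != "peptide_count":
        raise ValueError("peptide-count calling requires peptide_count tables")
    called: Set[str] = set()
    ratios: Dict[str, float] = {}
    for protein, peptides in ip.measurements.items():
        c = control.get(protein)
        if peptides > min_peptides and peptides > ratio * c:
            called.add(protein)
            ratios[protein] = _ratio(peptides, c)
    return PartnerSet(bait=ip.bait, proteins=called, ratios=ratios)


def call_partners_by_intensity(
    bait: MsTable, control: MsTable, ratio: float = 1.5
) -> PartnerSet:
    """Partner iff intensity > ratio * control intensity (strict).

    A protein with signal in the bait pull-down but absent from the control
    (control = 0) is included whenever its intensity is positive.
    """
    if (
        bait.assay_kind != "silac_intensity"
        or control.assay_kind != "silac_intensity"
    ):
        raise ValueError("intensity calling requires silac_intensity tables")
    called: Set[str] = set()
    ratios: Dict[str, float] = {}
    for protein, intensity in bait.measurements.items():
        c = control.get(protein)
        if intensity > ratio * c:
            called.add(protein)
            ratios[protein] = _ratio(intensity, c)
    return PartnerSet(bait=bait.bait, proteins=called, ratios=ratios)


def shared_partners(a: PartnerSet, b: PartnerSet) -> Set[str]:
    """Proteins called as partners of both baits."""
    return a.proteins & b.proteins


def idr_fraction_summary(
    proteins: Iterable[str],
    disorder_annotation: Mapping[str, Iterable[bool]],
) -> pd.DataFrame:
    """Per-protein fraction of intrinsically disordered residues, ranked.

    ``disorder_annotation`` maps protein id to a per-residue boolean
    disorder call (an upstream prediction, consumed as input). Returns a
    DataFrame indexed by protein, sorted by descending fraction.
    """
    rows = {}
    for protein in proteins:
        if protein not in disorder_annotation:
            raise KeyError(f"no disorder annotation for protein {protein}")
        mask = [bool(x) for x in disorder_annotation[protein]]
        if not mask:
            raise ValueError(f"empty disorder annotation for {protein}")
        rows[protein] = {
            "n_residues": len(mask),
            "n_disordered": sum(mask),
            "idr_fraction": sum(mask) / len(mask),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.sort_values("idr_fraction", ascending=False, kind="stable")
    df["rank"] = range(1, len(df) + 1)
    return df
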