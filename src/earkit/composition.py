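"""Residue-composition statistics of antibody-bound epitopes.

Epitope residue sets are consumed from pre-extracted tables (one residue
string per crystal structure).  Per-epitope relative frequencies are
count / epitope size as percent; averaging over epitopes is unweighted; the
combined frequency of a residue group (e.g. Y+W+F or N+Q+E) is the unweighted
mean of the group's per-residue percentages.  Structures are ranked as
Type I candidates by Y+W+F excess over N+Q+E and as Type II candidates by the
opposite excess; serine and alanine stay out of the Type II group because
they are generally enriched in protein-protein contacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .errors import FormatError, InputError
from .scales import AMINO_ACIDS, validate_sequence

TYPE_I_RESIDUES = frozenset("YWF")
TYPE_II_RESIDUES = frozenset("NQE")  # S and A deliberately excluded


@dataclass
class EpitopeResidueSet:
    """The epitope residues of one antibody-antigen structure (order irrelevant)."""

    structure_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"{self.structure_id}: empty epitope residue string")
        object.__setattr__(self, "residues", validate_sequence(self.residues))


#: A composition profile maps each residue to its relative frequency in percent.
CompositionProfile = Dict[str, float]


def epitope_composition(epitope: EpitopeResidueSet) -> CompositionProfile:
    """Per-residue relative frequencies (percent) within one epitope."""
    n = len(epitope.residues)
    profile = {aa: 0.0 for aa in AMINO_ACIDS}
    for aa in epitope.residues:
        profile[aa] += 100.0 / n
    return profile


def average_compositions(profiles: Sequence[CompositionProfile]) -> CompositionProfile:
    """Unweighted per-residue mean over epitopes."""
    if not profiles:
        raise InputError("cannot average an empty list of profiles")
    return {
        aa: sum(p.get(aa, 0.0) for p in profiles) / len(profiles)
        for aa in AMINO_ACIDS
    }


def combined_frequency(profile: CompositionProfile, residue_set: Iterable[str]) -> float:
    """Unweighted mean of the per-residue percentages over *residue_set*."""
    residues = [validate_sequence(r) for r in residue_set]
    if not residues:
        raise InputError("residue set must be non-empty")
    return sum(profile.get(r, 0.0) for r in residues) / len(residues)


@dataclass
class StructureEnrichment:
    structure_id: str
    ywf_combined: float
    nqe_combined: float


def rank_structures(
    structures: Sequence[StructureEnrichment],
) -> Tuple[List[StructureEnrichment], List[StructureEnrichment]]:
    """Candidate rankings: Type I by descending (Y+W+F − N+Q+E), Type II by
    descending (N+Q+E − Y+W+F); ties broken by structure id."""
    type_I = sorted(
        structures,
        key=lambda s: (-(s.ywf_combined - s.nqe_combined), s.structure_id),
    )
    type_II = sorted(
        structures,
        key=lambda s: (-(s.nqe_combined - s.ywf_combined), s.structure_id),
    )
    return list(type_I), list(type_II)


def enrichment_of(epitope: EpitopeResidueSet) -> StructureEnrichment:
    profile = epitope_composition(epitope)
    return StructureEnrichment(
        structure_id=epitope.structure_id,
        ywf_combined=combined_frequency(profile, TYPE_I_RESIDUES),
        nqe_combined=combined_frequency(profile, TYPE_II_RESIDUES),
    )


def read_epitope_table(path) -> List[EpitopeResidueSet]:
    """Read a TSV with columns ``structure_id`` and ``epitope_residues``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("structure_id", "epitope_residues"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return [
        EpitopeResidueSet(structure_id=str(r.structure_id), residues=str(r.epitope_residues))
        for r in df.itertuples()
    ]


def write_enrichment_table(enrichments: Sequence[StructureEnrichment], path) -> None:
    pd.DataFrame(
        [(e.structure_id, e.ywf_combined, e.nqe_combined) for e in enrichments],
        columns=["structure_id", "ywf_combined_pct", "nqe_combined_pct"],
    ).to_csv(path, sep="\t", index=False)
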