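"""Amino-acid property scales used by the interpretable and physico-chemical features.

The registry holds one :class:`PropertyScale` per named property.  Each scale
maps every one of the 20 standard residues to a real number; peptide-level
attributes are means of these values over the residues of a peptide.

Default sources: Kyte–Doolittle (hydrophobicity), Grantham (polarity),
Chou–Fasman (beta-sheet and reverse-turn conformational preferences), Levitt
(occurrence in turns), Welling (antigenicity) and the Atchley five-factor
solution of several hundred amino-acid indices, whose factors II and V serve
as the two "summary factor" attributes.  Aromaticity and acidity are indicator
scales over {F, W, Y} and {D, E}: their peptide means are the fractions of
aromatic and acidic residues.  All scales can be replaced or extended through
:func:`register_scale`, so the registry doubles as a configuration surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

from .errors import ConfigurationError, ResidueError

#: The 20 standard residues, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: Dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def validate_sequence(sequence: str) -> str:
    """Return *sequence* uppercased, or raise :class:`ResidueError`."""
    seq = sequence.upper()
    for ch in seq:
        if ch not in AA_INDEX:
            raise ResidueError(
                f"non-standard residue {ch!r} in sequence {sequence!r}"
            )
    return seq


@dataclass(frozen=True)
class PropertyScale:
    """A named mapping from each standard residue to a real number."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise ConfigurationError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def mean(self, sequence: str) -> float:
        seq = validate_sequence(sequence)
        return sum(self.values[aa] for aa in seq) / len(seq)


def _scale(name: str, values: Dict[str, float]) -> PropertyScale:
    return PropertyScale(name=name, values=values)


_KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

_GRANTHAM_POLARITY = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2,
    "G": 9.0, "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9,
    "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5, "R": 10.5,
    "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}

_CHOU_FASMAN_BETA = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
    "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
    "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
}

_CHOU_FASMAN_TURN = {
    "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.60,
    "G": 1.56, "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59,
    "M": 0.60, "N": 1.56, "P": 1.52, "Q": 0.98, "R": 0.95,
    "S": 1.43, "T": 0.96, "V": 0.50, "W": 0.96, "Y": 1.14,
}

_LEVITT_TURN = {
    "A": 0.77, "C": 0.81, "D": 1.41, "E": 0.99, "F": 0.59,
    "G": 1.64, "H": 0.68, "I": 0.51, "K": 0.96, "L": 0.58,
    "M": 0.41, "N": 1.28, "P": 1.91, "Q": 0.98, "R": 0.88,
    "S": 1.32, "T": 1.04, "V": 0.47, "W": 0.76, "Y": 1.05,
}

_WELLING_ANTIGENICITY = {
    "A": 1.15, "C": -1.20, "D": 0.65, "E": -0.71, "F": -1.41,
    "G": -1.84, "H": 3.12, "I": -2.92, "K": 2.06, "L": 0.75,
    "M": -3.85, "N": -0.77, "P": -0.53, "Q": -0.11, "R": 0.58,
    "S": -0.26, "T": -0.45, "V": -0.13, "W": -1.14, "Y": 0.13,
}

# Atchley et al. five-factor scores; factor II tracks secondary-structure
# propensity (coil/turn vs helix/sheet), factor V electrostatic character.
_ATCHLEY_FACTOR_2 = {
    "A": -1.302, "C": 0.465, "D": 0.302, "E": -1.453, "F": -0.590,
    "G": 1.652, "H": -0.417, "I": -0.547, "K": -0.561, "L": -0.987,
    "M": -1.524, "N": 0.828, "P": 2.081, "Q": -0.179, "R": -0.055,
    "S": 1.399, "T": 0.326, "V": -0.279, "W": 0.009, "Y": 0.830,
}

_ATCHLEY_FACTOR_5 = {
    "A": -0.146, "C": -0.255, "D": -3.242, "E": -0.837, "F": 0.412,
    "G": 2.064, "H": -0.078, "I": 0.816, "K": 1.648, "L": -0.912,
    "M": 1.212, "N": 0.933, "P": -1.392, "Q": -1.853, "R": 2.897,
    "S": -2.647, "T": 1.313, "V": -1.262, "W": -0.184, "Y": 1.512,
}

AROMATIC_RESIDUES = frozenset("FWY")
ACIDIC_RESIDUES = frozenset("DE")

_AROMATICITY = {aa: (1.0 if aa in AROMATIC_RESIDUES else 0.0) for aa in AMINO_ACIDS}
_ACIDITY = {aa: (1.0 if aa in ACIDIC_RESIDUES else 0.0) for aa in AMINO_ACIDS}

#: Canonical attribute names used by rule summaries and feature builders.
SCALE_REGISTRY: Dict[str, PropertyScale] = {}


def register_scale(scale: PropertyScale, replace: bool = False) -> None:
    """Add *scale* to the registry (``replace=True`` to overwrite)."""
    if scale.name in SCALE_REGISTRY and not replace:
        raise ConfigurationError(f"scale {scale.name!r} already registered")
    SCALE_REGISTRY[scale.name] = scale


for _s in (
    _scale("aromaticity", _AROMATICITY),
    _scale("polarity", _GRANTHAM_POLARITY),
    _scale("hydrophobicity", _KYTE_DOOLITTLE),
    _scale("acidity", _ACIDITY),
    _scale("beta-sheet preference", _CHOU_FASMAN_BETA),
    _scale("reverse-turn preference", _CHOU_FASMAN_TURN),
    _scale("occurrence in turns", _LEVITT_TURN),
    _scale("antigenicity", _WELLING_ANTIGENICITY),
    _scale("summary factor 2", _ATCHLEY_FACTOR_2),
    _scale("summary factor 5", _ATCHLEY_FACTOR_5),
):
    register_scale(_s)


def get_scale(name: str) -> PropertyScale:
    try:
        return SCALE_REGISTRY[name]
    except KeyError:
        raise ConfigurationError(f"unknown property scale {name!r}") from None


def scale_names() -> Iterable[str]:
    return tuple(SCALE_REGISTRY)
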