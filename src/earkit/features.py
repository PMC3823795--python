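"""Peptide attribute representations.

Eight attribute families describe a peptide for the ensemble classifier:

1. frequencies of the 20 amino acids,
2. pairwise differences between those frequencies,
3. frequencies of amino-acid subsequences up to length ``k_max``,
4. peptide means of physico-chemical property scales,
5. frequencies of physico-chemical amino-acid classes,
6. frequencies of class subsequences up to length ``class_k_max``,
7. frequencies of residue pairs at a fixed separation up to ``d_max``,
8. indicators of which residue occupies each position (offset from the
   first position).

Subsequence/pair frequencies are counts divided by the number of windows of
the relevant size (length ``L-k+1`` for k-mers, ``L-d`` for pairs at distance
``d``), so values are comparable across peptide lengths.

The *interpretable* attribute set used for rule induction and stratification
concatenates subsequence frequencies up to length 5 with all property-scale
means; single-residue attributes carry readable names such as
``"frequency of tyrosine"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError
from .scales import (
    AA_INDEX,
    AMINO_ACIDS,
    SCALE_REGISTRY,
    get_scale,
    validate_sequence,
)

#: Physico-chemical residue classes (a partition of the alphabet).
CLASS_PARTITION: Dict[str, str] = {}
for _cls, _members in (
    ("acidic", "DE"),
    ("basic", "KRH"),
    ("aromatic", "FWY"),
    ("polar-uncharged", "STNQC"),
    ("small-nonpolar", "AGP"),
    ("aliphatic-hydrophobic", "ILMV"),
):
    for _aa in _members:
        CLASS_PARTITION[_aa] = _cls

CLASS_NAMES: Tuple[str, ...] = (
    "acidic",
    "basic",
    "aromatic",
    "polar-uncharged",
    "small-nonpolar",
    "aliphatic-hydrophobic",
)

AA_NAMES: Dict[str, str] = {
    "A": "alanine", "C": "cysteine", "D": "aspartic acid", "E": "glutamic acid",
    "F": "phenylalanine", "G": "glycine", "H": "histidine", "I": "isoleucine",
    "K": "lysine", "L": "leucine", "M": "methionine", "N": "asparagine",
    "P": "proline", "Q": "glutamine", "R": "arginine", "S": "serine",
    "T": "threonine", "V": "valine", "W": "tryptophan", "Y": "tyrosine",
}


def class_partition_of(residue: str) -> str:
    """Physico-chemical class of a standard residue."""
    res = validate_sequence(residue)
    if len(res) != 1:
        raise ConfigurationError("class_partition_of expects a single residue")
    return CLASS_PARTITION[res]


@dataclass(frozen=True)
class AttributeFamilySpec:
    """Identifies one of the eight attribute families plus its parameters.

    ``params`` keys (used per family): ``k_max`` (family 3, default 3),
    ``scales`` (family 4, default: all registered scales), ``class_k_max``
    (family 6, default 4), ``d_max`` (family 7, default 7), ``length``
    (family 8, default 15).
    """

    family_id: int
    params: Tuple[Tuple[str, object], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.family_id not in range(1, 9):
            raise ConfigurationError(f"family_id must be 1..8, got {self.family_id}")

    @property
    def param_dict(self) -> Dict[str, object]:
        return dict(self.params)

    @staticmethod
    def make(family_id: int, **params) -> "AttributeFamilySpec":
        return AttributeFamilySpec(family_id, tuple(sorted(params.items())))


def default_family_specs() -> List[AttributeFamilySpec]:
    """The eight families with their default parameters."""
    return [AttributeFamilySpec.make(i) for i in range(1, 9)]


def _aa_counts(seq: str) -> np.ndarray:
    counts = np.zeros(20)
    for aa in seq:
        counts[AA_INDEX[aa]] += 1
    return counts


def _kmer_names(k: int, alphabet: Sequence[str]) -> List[str]:
    return ["".join(t) for t in itertools.product(alphabet, repeat=k)]


def attribute_names(spec: AttributeFamilySpec) -> List[str]:
    """Column names for *spec*; fixed for a given spec, independent of peptides."""
    p = spec.param_dict
    fid = spec.family_id
    if fid == 1:
        return [f"freq[{aa}]" for aa in AMINO_ACIDS]
    if fid == 2:
        return [
            f"freq[{a}]-freq[{b}]"
            for a, b in itertools.combinations(AMINO_ACIDS, 2)
        ]
    if fid == 3:
        k_max = int(p.get("k_max", 3))
        names = []
        for k in range(1, k_max + 1):
            names.extend(f"freq[{m}]" for m in _kmer_names(k, AMINO_ACIDS))
        return names
    if fid == 4:
        scales = p.get("scales") or tuple(SCALE_REGISTRY)
        return [f"mean[{s}]" for s in scales]
    if fid == 5:
        return [f"classfreq[{c}]" for c in CLASS_NAMES]
    if fid == 6:
        class_k_max = int(p.get("class_k_max", 4))
        names = []
        for k in range(1, class_k_max + 1):
            names.extend(
                "classfreq[" + "|".join(t) + "]"
                for t in itertools.product(CLASS_NAMES, repeat=k)
            )
        return names
    if fid == 7:
        d_max = int(p.get("d_max", 7))
        return [
            f"pair[{a}{b}]@{d}"
            for d in range(1, d_max + 1)
            for a in AMINO_ACIDS
            for b in AMINO_ACIDS
        ]
    # family 8: residue indicator at each offset from the first position
    length = int(p.get("length", 15))
    return [f"is[{aa}]@{off}" for off in range(length) for aa in AMINO_ACIDS]


def build_attribute_vector(peptide: str, spec: AttributeFamilySpec) -> np.ndarray:
    """The attribute vector of one peptide under *spec* (order per
    :func:`attribute_names`)."""
    seq = validate_sequence(peptide)
    p = spec.param_dict
    fid = spec.family_id
    L = len(seq)
    if fid == 1:
        return _aa_counts(seq) / L
    if fid == 2:
        f = _aa_counts(seq) / L
        idx = list(itertools.combinations(range(20), 2))
        return np.array([f[i] - f[j] for i, j in idx])
    if fid == 3:
        k_max = int(p.get("k_max", 3))
        parts = []
        for k in range(1, k_max + 1):
            vec = np.zeros(20 ** k)
            n_windows = L - k + 1
            if n_windows > 0:
                for i in range(n_windows):
                    code = 0
                    for aa in seq[i : i + k]:
                        code = code * 20 + AA_INDEX[aa]
                    vec[code] += 1
                vec /= n_windows
            parts.append(vec)
        return np.concatenate(parts)
    if fid == 4:
        scales = p.get("scales") or tuple(SCALE_REGISTRY)
        return np.array([get_scale(s).mean(seq) for s in scales])
    if fid == 5:
        vec = np.zeros(len(CLASS_NAMES))
        cls_idx = {c: i for i, c in enumerate(CLASS_NAMES)}
        for aa in seq:
            vec[cls_idx[CLASS_PARTITION[aa]]] += 1
        return vec / L
    if fid == 6:
        class_k_max = int(p.get("class_k_max", 4))
        cls_idx = {c: i for i, c in enumerate(CLASS_NAMES)}
        codes = [cls_idx[CLASS_PARTITION[aa]] for aa in seq]
        n_classes = len(CLASS_NAMES)
        parts = []
        for k in range(1, class_k_max + 1):
            vec = np.zeros(n_classes ** k)
            n_windows = L - k + 1
            if n_windows > 0:
                for i in range(n_windows):
                    code = 0
                    for c in codes[i : i + k]:
                        code = code * n_classes + c
                    vec[code] += 1
                vec /= n_windows
            parts.append(vec)
        return np.concatenate(parts)
    if fid == 7:
        d_max = int(p.get("d_max", 7))
        parts = []
        for d in range(1, d_max + 1):
            vec = np.zeros(400)
            n_windows = L - d
            if n_windows > 0:
                for i in range(n_windows):
                    vec[AA_INDEX[seq[i]] * 20 + AA_INDEX[seq[i + d]]] += 1
                vec /= n_windows
            parts.append(vec)
        return np.concatenate(parts)
    length = int(p.get("length", 15))
    vec = np.zeros(length * 20)
    for off in range(min(L, length)):
        vec[off * 20 + AA_INDEX[seq[off]]] = 1.0
    return vec


@dataclass
class FeatureMatrix:
    """A dense peptide-by-attribute matrix."""

    peptide_ids: List[str]
    attribute_names: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.values.shape
        if n != len(self.peptide_ids) or m != len(self.attribute_names):
            raise ConfigurationError("feature matrix shape does not match labels")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.attribute_names.index(name)]

    def subset_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            [self.peptide_ids[i] for i in idx],
            list(self.attribute_names),
            self.values[idx],
        )


def build_feature_matrix(
    peptides: Sequence[Tuple[str, str]], spec: AttributeFamilySpec
) -> FeatureMatrix:
    """Feature matrix for ``(peptide_id, sequence)`` pairs under one family spec."""
    names = attribute_names(spec)
    values = np.empty((len(peptides), len(names)))
    for i, (_, seq) in enumerate(peptides):
        values[i] = build_attribute_vector(seq, spec)
    return FeatureMatrix([pid for pid, _ in peptides], names, values)


def _readable_kmer_name(kmer: str) -> str:
    if len(kmer) == 1:
        return f"frequency of {AA_NAMES[kmer]}"
    return f"frequency of subsequence {kmer}"


def interpretable_attributes(peptide: str, k_max: int = 5) -> Dict[str, float]:
    """Interpretable attributes of one peptide: subsequence frequencies up to
    length *k_max* (only subsequences present in the peptide; absent ones are
    zero by definition) plus all property-scale means."""
    seq = validate_sequence(peptide)
    out: Dict[str, float] = {}
    for aa in AMINO_ACIDS:  # single-residue frequencies always reported
        out[_readable_kmer_name(aa)] = 0.0
    L = len(seq)
    for k in range(1, k_max + 1):
        n_windows = L - k + 1
        if n_windows <= 0:
            break
        for i in range(n_windows):
            name = _readable_kmer_name(seq[i : i + k])
            out[name] = out.get(name, 0.0) + 1.0 / n_windows
    for sname, scale in SCALE_REGISTRY.items():
        out[sname] = scale.mean(seq)
    return out


def interpretable_feature_matrix(
    peptides: Sequence[Tuple[str, str]],
    k_max: int = 5,
    vocabulary: Optional[List[str]] = None,
) -> FeatureMatrix:
    """Interpretable-attribute matrix over a peptide list.

    The subsequence vocabulary defaults to every subsequence (up to *k_max*)
    observed in the input; pass the ``attribute_names`` of a previously built
    matrix as *vocabulary* to represent new peptides in the same space.
    """
    dicts = [interpretable_attributes(seq, k_max=k_max) for _, seq in peptides]
    if vocabulary is None:
        names: List[str] = []
        seen = set()
        for d in dicts:
            for name in d:
                if name not in seen:
                    seen.add(name)
                    names.append(name)
        names.sort()
    else:
        names = list(vocabulary)
    index = {name: j for j, name in enumerate(names)}
    values = np.zeros((len(peptides), len(names)))
    for i, d in enumerate(dicts):
        for name, v in d.items():
            j = index.get(name)
            if j is not None:
                values[i, j] = v
    return FeatureMatrix([pid for pid, _ in peptides], names, values)
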