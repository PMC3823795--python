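"""Peptide-chip table parsing, signal preprocessing and class assignment.

A chip experiment measures each displayed peptide in triplicate under two
stainings: the IVIG antibody preparation plus a fluorescent secondary
antibody, and the secondary antibody alone (per-peptide background).  This
module turns such raw tables into labeled peptides:

1. replicate intensities are averaged per peptide,
2. peptides whose secondary-only signal exceeds the IVIG signal are removed
   (direct secondary-antibody binders, i.e. false positives),
3. duplicate sequences keep the measurement with the highest IVIG mean,
4. the background-corrected net signal classifies peptides as *binding*
   (net > 10,000), *non-binding* (net <= 100) or *unassigned* (in between),
5. the assignable peptides can be split in half, stratified by class, and
   rebalanced by random over- or undersampling.

Intensities are 16-bit scanner units, valid range 0..65535.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, FormatError, InputError, StratificationError
from .scales import validate_sequence

INTENSITY_MAX = 65535.0

BINDING = "binding"
NON_BINDING = "non-binding"
UNASSIGNED = "unassigned"

#: Default net-signal thresholds (fluorescence units).
BINDER_THRESHOLD = 10_000.0
NONBINDER_THRESHOLD = 100.0


@dataclass
class ChipRecord:
    """One row of a chip table: a peptide with its replicate intensities."""

    peptide_id: str
    sequence: str
    source: str
    ivig_replicates: List[float]
    secondary_replicates: List[float]
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if not self.ivig_replicates or not self.secondary_replicates:
            raise InputError(f"{self.peptide_id}: replicate lists must be non-empty")
        for v in (*self.ivig_replicates, *self.secondary_replicates):
            if not np.isnan(v) and not (0.0 <= v <= INTENSITY_MAX):
                raise InputError(
                    f"{self.peptide_id}: intensity {v} outside [0, {INTENSITY_MAX:.0f}]"
                )

    @property
    def ivig_mean(self) -> float:
        return float(np.nanmean(self.ivig_replicates))

    @property
    def secondary_mean(self) -> float:
        return float(np.nanmean(self.secondary_replicates))


@dataclass
class ProcessedPeptide:
    """A unique sequence with averaged signals and net (background-corrected) signal."""

    peptide_id: str
    sequence: str
    ivig_mean: float
    secondary_mean: float

    @property
    def net_signal(self) -> float:
        return self.ivig_mean - self.secondary_mean


@dataclass
class LabeledPeptide:
    """A peptide with its binding class."""

    peptide_id: str
    sequence: str
    label: str
    net_signal: float


@dataclass
class DataSplit:
    """A stratified half/half split into training and test sets."""

    train: List[LabeledPeptide]
    test: List[LabeledPeptide]
    seed: int = 0


_IVIG_COL = re.compile(r"^ivig_(\d+)$")
_SEC_COL = re.compile(r"^sec_(\d+)$")
_REQUIRED = ("peptide_id", "sequence", "source", "experiment_id")


def read_chip_table(path) -> List[ChipRecord]:
    """Parse a tab-separated chip table into :class:`ChipRecord` rows.

    Expected columns: ``peptide_id``, ``sequence``, ``source``,
    ``ivig_1..ivig_k``, ``sec_1..sec_k``, ``experiment_id``.  Lines starting
    with ``#`` are comments.  Malformed rows are reported with their line
    numbers in a single :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"peptide_id": str})
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    ivig_cols = sorted(
        (c for c in df.columns if _IVIG_COL.match(c)),
        key=lambda c: int(_IVIG_COL.match(c).group(1)),
    )
    sec_cols = sorted(
        (c for c in df.columns if _SEC_COL.match(c)),
        key=lambda c: int(_SEC_COL.match(c).group(1)),
    )
    if not ivig_cols or not sec_cols:
        raise FormatError(f"{path}: no ivig_*/sec_* replicate columns found")

    records: List[ChipRecord] = []
    problems: List[str] = []
    for idx, row in df.iterrows():
        # +2: header line plus 1-based numbering (comment lines not counted).
        line_no = int(idx) + 2
        try:
            ivig = [float(row[c]) for c in ivig_cols]
            sec = [float(row[c]) for c in sec_cols]
            records.append(
                ChipRecord(
                    peptide_id=str(row["peptide_id"]),
                    sequence=validate_sequence(str(row["sequence"])),
                    source=str(row["source"]),
                    ivig_replicates=ivig,
                    secondary_replicates=sec,
                    experiment_id=str(row["experiment_id"]),
                )
            )
        except (ValueError, InputError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise FormatError(f"{path}: {len(problems)} malformed row(s):\n" + "\n".join(problems))
    return records


def records_from_frame(chip: pd.DataFrame) -> List[ChipRecord]:
    """Build :class:`ChipRecord` rows from an in-memory chip table (same
    columns as :func:`read_chip_table` expects)."""
    ivig_cols = sorted(
        (c for c in chip.columns if _IVIG_COL.match(c)),
        key=lambda c: int(_IVIG_COL.match(c).group(1)),
    )
    sec_cols = sorted(
        (c for c in chip.columns if _SEC_COL.match(c)),
        key=lambda c: int(_SEC_COL.match(c).group(1)),
    )
    if not ivig_cols or not sec_cols:
        raise FormatError("no ivig_*/sec_* replicate columns found")
    return [
        ChipRecord(
            peptide_id=str(row.peptide_id),
            sequence=validate_sequence(str(row.sequence)),
            source=str(row.source),
            ivig_replicates=[float(getattr(row, c)) for c in ivig_cols],
            secondary_replicates=[float(getattr(row, c)) for c in sec_cols],
            experiment_id=str(row.experiment_id),
        )
        for row in chip.itertuples()
    ]


def preprocess_records(records: Sequence[ChipRecord]) -> List[ProcessedPeptide]:
    """Average replicates, drop secondary-antibody artifacts, collapse duplicates.

    A record is removed when its secondary-only mean is strictly larger than
    its IVIG mean (ties retained).  Duplicate sequences keep the record with
    the highest IVIG mean; ties keep the first occurrence in file order.
    """
    best: Dict[str, ProcessedPeptide] = {}
    order: List[str] = []
    for rec in records:
        ivig, sec = rec.ivig_mean, rec.secondary_mean
        if sec > ivig:
            continue
        prev = best.get(rec.sequence)
        if prev is None:
            best[rec.sequence] = ProcessedPeptide(rec.peptide_id, rec.sequence, ivig, sec)
            order.append(rec.sequence)
        elif ivig > prev.ivig_mean:
            best[rec.sequence] = ProcessedPeptide(rec.peptide_id, rec.sequence, ivig, sec)
    return [best[seq] for seq in order]


def assign_classes(
    peptides: Sequence[ProcessedPeptide],
    binder_threshold: float = BINDER_THRESHOLD,
    nonbinder_threshold: float = NONBINDER_THRESHOLD,
) -> List[LabeledPeptide]:
    """Label peptides binding (net > binder_threshold), non-binding
    (net <= nonbinder_threshold) or unassigned (in between, boundary at the
    binder threshold included)."""
    if not nonbinder_threshold < binder_threshold:
        raise ConfigurationError(
            f"nonbinder threshold {nonbinder_threshold} must be below "
            f"binder threshold {binder_threshold}"
        )
    out = []
    for p in peptides:
        net = p.net_signal
        if net > binder_threshold:
            label = BINDING
        elif net <= nonbinder_threshold:
            label = NON_BINDING
        else:
            label = UNASSIGNED
        out.append(LabeledPeptide(p.peptide_id, p.sequence, label, net))
    return out


def _by_class(peptides: Sequence[LabeledPeptide]) -> Dict[str, List[int]]:
    groups: Dict[str, List[int]] = {}
    for i, p in enumerate(peptides):
        groups.setdefault(p.label, []).append(i)
    return groups


def split_train_test(peptides: Sequence[LabeledPeptide], seed: int) -> DataSplit:
    """Split in half by random sampling, stratified by class.

    Each class is shuffled and halved; an odd class count puts the extra
    peptide into the test half.
    """
    groups = _by_class(peptides)
    if any(len(idx) == 0 for idx in groups.values()) or not groups:
        raise StratificationError("cannot split: a class is empty")
    rng = np.random.default_rng(seed)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for label in sorted(groups):
        idx = np.array(groups[label])
        rng.shuffle(idx)
        half = len(idx) // 2
        train_idx.extend(idx[:half])
        test_idx.extend(idx[half:])
    train_idx.sort()
    test_idx.sort()
    return DataSplit(
        train=[peptides[i] for i in train_idx],
        test=[peptides[i] for i in test_idx],
        seed=seed,
    )


def rebalance(
    peptides: Sequence[LabeledPeptide], mode: str, seed: int
) -> List[LabeledPeptide]:
    """Equalize the two class counts by random over- or undersampling.

    ``oversample`` keeps every peptide and duplicates uniformly chosen
    minority peptides (with replacement) until the classes match;
    ``undersample`` drops uniformly chosen majority peptides (without
    replacement).
    """
    if mode not in ("oversample", "undersample"):
        raise ConfigurationError(f"unknown rebalance mode {mode!r}")
    groups = _by_class(peptides)
    if len(groups) != 2:
        raise InputError(f"rebalance requires exactly two classes, got {sorted(groups)}")
    (small_label, small), (big_label, big) = sorted(
        groups.items(), key=lambda kv: (len(kv[1]), kv[0])
    )
    if len(small) == len(big):
        return list(peptides)
    rng = np.random.default_rng(seed)
    if mode == "oversample":
        extra = rng.choice(np.array(small), size=len(big) - len(small), replace=True)
        keep = sorted([*range(len(peptides))] + [int(i) for i in extra])
    else:
        kept_big = rng.choice(np.array(big), size=len(small), replace=False)
        keep = sorted([*small, *(int(i) for i in kept_big)])
    return [peptides[i] for i in keep]


def read_fasta_peptides(path) -> List[Tuple[str, str]]:
    """Read a FASTA file of peptides as ``(identifier, sequence)`` pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, validate_sequence(str(rec.seq))))
    return out


def write_labeled_tsv(peptides: Iterable[LabeledPeptide], path) -> None:
    df = pd.DataFrame(
        [(p.peptide_id, p.sequence, p.label, p.net_signal) for p in peptides],
        columns=["peptide_id", "sequence", "label", "net_signal"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_labeled_tsv(path) -> List[LabeledPeptide]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str})
    for col in ("peptide_id", "sequence", "label", "net_signal"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return [
        LabeledPeptide(str(r.peptide_id), validate_sequence(str(r.sequence)),
                       str(r.label), float(r.net_signal))
        for r in df.itertuples()
    ]
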