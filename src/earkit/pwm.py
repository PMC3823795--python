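"""Position weight matrices for epitope propensity analysis and scoring.

For the binding and the non-binding peptide sets a 20 x L position frequency
matrix is built (L = 15 by default).  Their elementwise quotient is the
*ratio PWM*: entry (a, j) > 1 means residue *a* at position *j* is enriched
among binders.  A peptide's *PWM score* is the product over its positions of
the matching ratios (computed in log space, reported on the product scale);
scores above a threshold (default 2.45) classify the peptide as binding.

Additive smoothing with pseudocount 1 (applied identically to both matrices)
keeps every ratio finite and makes identical input sets give all-ones ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import ConfigurationError, InputError
from .scales import AA_INDEX, AMINO_ACIDS, validate_sequence

ENRICHED_RATIO = 2.0   # heat-map flag: residue/position enriched in binders
DEPLETED_RATIO = 0.7   # heat-map flag: depleted in binders
DEFAULT_THRESHOLD = 2.45
DEFAULT_LENGTH = 15


@dataclass
class FrequencyPWM:
    """Column-stochastic residue-frequency matrix with additive smoothing."""

    length: int
    counts: np.ndarray        # 20 x length, integers
    frequencies: np.ndarray   # 20 x length, columns sum to 1
    pseudocount: float
    n_sequences: int

    def frequency(self, residue: str, position: int) -> float:
        """Frequency of *residue* at 1-based *position*."""
        return float(self.frequencies[AA_INDEX[residue], position - 1])


@dataclass
class RatioPWM:
    """Binding : non-binding frequency ratios with per-residue propensities."""

    ratios: np.ndarray  # 20 x length, positive
    positional_propensity: np.ndarray  # length-20 row means

    @property
    def length(self) -> int:
        return self.ratios.shape[1]

    def ratio(self, residue: str, position: int) -> float:
        return float(self.ratios[AA_INDEX[residue], position - 1])

    @property
    def enriched(self) -> np.ndarray:
        """Boolean mask of cells enriched in binders (ratio > 2)."""
        return self.ratios > ENRICHED_RATIO

    @property
    def depleted(self) -> np.ndarray:
        """Boolean mask of cells depleted in binders (ratio < 0.7)."""
        return self.ratios < DEPLETED_RATIO


@dataclass
class PWMClassifier:
    """A ratio PWM plus a score threshold separating binders from non-binders."""

    ratio_pwm: RatioPWM
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ConfigurationError("PWM threshold must be positive")


def filter_to_length(
    sequences: Iterable[str], length: int = DEFAULT_LENGTH
) -> List[str]:
    """Keep only sequences of *length*; warn when any are dropped."""
    seqs = list(sequences)
    kept = [s for s in seqs if len(s) == length]
    if len(kept) < len(seqs):
        warnings.warn(
            f"excluded {len(seqs) - len(kept)} peptide(s) not of length {length} "
            "from PWM construction",
            stacklevel=2,
        )
    return kept


def build_frequency_pwm(
    peptides: Sequence[str], length: int = DEFAULT_LENGTH, pseudocount: float = 1.0
) -> FrequencyPWM:
    """Count residues per position and smooth: freq = (count + pc) / (n + 20 pc)."""
    if not peptides:
        raise InputError("cannot build a PWM from an empty peptide list")
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be nonnegative")
    counts = np.zeros((20, length))
    for seq in peptides:
        s = validate_sequence(seq)
        if len(s) != length:
            raise InputError(
                f"peptide {seq!r} has length {len(s)}, expected {length}"
            )
        for j, aa in enumerate(s):
            counts[AA_INDEX[aa], j] += 1
    n = len(peptides)
    frequencies = (counts + pseudocount) / (n + 20.0 * pseudocount)
    return FrequencyPWM(length, counts, frequencies, pseudocount, n)


def build_ratio_pwm(binding: FrequencyPWM, nonbinding: FrequencyPWM) -> RatioPWM:
    """Elementwise binding/non-binding frequency ratio plus row-mean propensities."""
    if binding.length != nonbinding.length:
        raise InputError("binding and non-binding PWMs differ in length")
    if binding.pseudocount != nonbinding.pseudocount:
        raise ConfigurationError(
            "binding and non-binding PWMs must use the same pseudocount"
        )
    if np.any(nonbinding.frequencies == 0):
        raise InputError(
            "zero frequencies in the non-binding PWM (pseudocount 0); "
            "ratios are undefined"
        )
    ratios = binding.frequencies / nonbinding.frequencies
    return RatioPWM(ratios=ratios, positional_propensity=ratios.mean(axis=1))


def global_propensity(
    binding: Sequence[str],
    nonbinding: Sequence[str],
    pseudocount: float = 1.0,
) -> Dict[str, float]:
    """Position-independent epitope propensity per residue.

    The overall residue frequency among binding peptides divided by the
    frequency among non-binding peptides, each additively smoothed with
    *pseudocount* over residue totals.  With ``pseudocount=0`` a residue that
    is absent from the non-binding peptides yields ``inf`` (or ``nan`` when
    absent from both sets).
    """
    if not binding or not nonbinding:
        raise InputError("both peptide lists must be non-empty")

    def _freq(seqs: Sequence[str]) -> np.ndarray:
        counts = np.zeros(20)
        total = 0
        for s in seqs:
            s = validate_sequence(s)
            total += len(s)
            for aa in s:
                counts[AA_INDEX[aa]] += 1
        return (counts + pseudocount) / (total + 20.0 * pseudocount)

    fb, fn = _freq(binding), _freq(nonbinding)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = fb / fn
    return {aa: float(ratios[i]) for aa, i in AA_INDEX.items()}


def pwm_score(peptide: str, classifier: PWMClassifier) -> Tuple[float, str]:
    """Product of positional ratios (log-space accumulation) and the label at
    the classifier threshold: ``"binding"`` iff score > threshold."""
    seq = validate_sequence(peptide)
    rp = classifier.ratio_pwm
    if len(seq) != rp.length:
        raise InputError(f"peptide length {len(seq)} does not match PWM length {rp.length}")
    log_score = 0.0
    for j, aa in enumerate(seq):
        log_score += np.log(rp.ratios[AA_INDEX[aa], j])
    score = float(np.exp(log_score))
    label = "binding" if score > classifier.threshold else "non-binding"
    return score, label


def pwm_scores(peptides: Sequence[str], classifier: PWMClassifier) -> np.ndarray:
    """Vector of PWM scores (product scale) for many peptides."""
    rp = classifier.ratio_pwm
    log_ratios = np.log(rp.ratios)
    out = np.empty(len(peptides))
    for i, pep in enumerate(peptides):
        seq = validate_sequence(pep)
        if len(seq) != rp.length:
            raise InputError(
                f"peptide length {len(seq)} does not match PWM length {rp.length}"
            )
        out[i] = sum(log_ratios[AA_INDEX[aa], j] for j, aa in enumerate(seq))
    return np.exp(out)


def calibrate_threshold(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Accuracy-maximizing score threshold (label ``binding`` iff score > t).

    Candidates are midpoints between adjacent distinct scores plus sentinels;
    ties favor the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.array([1 if l == "binding" else 0 for l in labels])
    order = np.argsort(scores)
    s_sorted = scores[order]
    uniq = np.unique(s_sorted)
    candidates = [uniq[0] / 2 if uniq[0] > 0 else uniq[0] - 1.0]
    candidates += [(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])]
    candidates.append(uniq[-1] + 1.0)
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = np.mean((scores > t) == (y == 1))
        if acc > best_acc:
            best_t, best_acc = float(t), float(acc)
    return best_t


def export_heatmap_matrix(
    ratio: RatioPWM, cluster: bool = False
) -> Tuple[np.ndarray, List[int], List[int]]:
    """Matrix plus row/column orderings for a ratio heat map.

    With ``cluster`` the orderings come from average-linkage hierarchical
    clustering on Euclidean distances (rows: residues, columns: positions);
    otherwise they are the native orders.  Values are never altered.
    """
    m = ratio.ratios
    if not cluster:
        return m, list(range(m.shape[0])), list(range(m.shape[1]))
    row_order = [int(i) for i in leaves_list(linkage(m, method="average", metric="euclidean"))]
    col_order = [int(i) for i in leaves_list(linkage(m.T, method="average", metric="euclidean"))]
    return m, row_order, col_order


def pwm_to_tsv(matrix: np.ndarray, path, length: Optional[int] = None) -> None:
    """Serialize a 20 x L matrix, rows A..Y alphabetical, columns pos1..posL."""
    length = length or matrix.shape[1]
    df = pd.DataFrame(
        matrix,
        index=list(AMINO_ACIDS),
        columns=[f"pos{j}" for j in range(1, length + 1)],
    )
    df.to_csv(path, sep="\t", index_label="residue")


def pwm_from_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col="residue")
    if list(df.index) != list(AMINO_ACIDS):
        raise InputError(f"{path}: rows must be the 20 residues A..Y in order")
    return df.to_numpy(dtype=float)
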