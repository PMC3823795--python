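"""Synthetic peptide-chip generator with the statistical structure the
analysis pipeline assumes.

The generator emulates an IVIG peptide-microarray screen:

* roughly three non-binding peptides per binding peptide among the
  assignable peptides (binder fraction 0.25),
* a majority *Type I* binder subpopulation enriched in Y/W/F and depleted in
  N/Q/E/S/A, and a minority *Type II* binder subpopulation with the opposite
  bias (default 18% of binders, inside the 15-20% band the stratification
  analysis expects),
* non-binders mirror the binder structure: a majority depleted in Y/W/F and
  a smaller minority (8%) with Type-I-like composition.  The minority is kept
  small enough that binders dominate among aromatic-rich peptides
  (posterior ~0.77), so a whole-set composition classifier confidently calls
  aromatic-rich peptides binding and aromatic-poor peptides non-binding —
  and therefore systematically fails on exactly the two minority
  subpopulations, reproducing a 15-20% unclassifiable remainder whose
  internal composition rule is inverted,
* log-normal signal intensities straddling the 100 / 10,000 net-signal
  thresholds, measured as triplicates with multiplicative noise, plus a
  small unassigned band in between,
* a fraction of rows whose secondary-antibody-only signal exceeds the IVIG
  signal (removed by preprocessing as artifacts).

Optional position effects place class-specific residue preferences at chosen
positions while keeping the overall composition of the two classes identical
— the regime in which PWM rescue succeeds where composition features fail.

Ground truth (class, subpopulation, artifact flag) is emitted as a separate
table so pipeline stages cannot peek.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scales import AA_INDEX, AMINO_ACIDS

PEPTIDE_LENGTH = 15


@dataclass(frozen=True)
class PositionEffect:
    """Class-specific residue preferences at fixed positions (0-based).

    Binders prefer ``residues[i]`` at ``positions[i]``; non-binders see the
    same residues in reverse order, so the overall residue composition of the
    two classes stays identical while their positional structure differs.
    """

    positions: Tuple[int, ...]
    residues: Tuple[str, ...]
    weight: float = 20.0

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.residues):
            raise ConfigurationError("positions and residues must align")
        if len(self.positions) < 2:
            raise ConfigurationError("a position effect needs at least two positions")
        if self.weight <= 0:
            raise ConfigurationError("position-effect weight must be positive")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic chip experiment."""

    n_peptides: int
    seed: int = 0
    binder_fraction: float = 0.25
    type2_fraction: float = 0.18
    nonbinder_minority_fraction: float = 0.08
    unassigned_fraction: float = 0.05
    secondary_artifact_rate: float = 0.05
    enrich_weight: float = 3.0
    deplete_weight: float = 1.0 / 3.0
    up_residues: str = "YWF"
    down_residues: str = "NQESA"
    position_effect: Optional[PositionEffect] = None
    length: int = PEPTIDE_LENGTH
    n_replicates: int = 3
    replicate_cv: float = 0.02
    # log-normal medians / log-scale sigmas of intended net signals
    binder_median: float = 20_000.0
    binder_sigma: float = 0.25
    nonbinder_median: float = 30.0
    nonbinder_sigma: float = 0.4
    unassigned_median: float = 1_000.0
    unassigned_sigma: float = 0.6
    secondary_median: float = 20.0
    secondary_sigma: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "binder_fraction", "type2_fraction", "nonbinder_minority_fraction",
            "unassigned_fraction", "secondary_artifact_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.enrich_weight <= 0 or self.deplete_weight <= 0:
            raise ConfigurationError("composition weights must be positive")


def _biased_weights(cfg: SyntheticConfig, invert: bool) -> np.ndarray:
    w = np.ones(20)
    up = cfg.deplete_weight if invert else cfg.enrich_weight
    down = cfg.enrich_weight if invert else cfg.deplete_weight
    for aa in cfg.up_residues:
        w[AA_INDEX[aa]] *= up
    for aa in cfg.down_residues:
        w[AA_INDEX[aa]] *= down
    return w


def subpopulation_weights(cfg: SyntheticConfig) -> Dict[str, np.ndarray]:
    """Residue sampling weights per subpopulation (unnormalized)."""
    return {
        "type_I": _biased_weights(cfg, invert=False),
        "type_II": _biased_weights(cfg, invert=True),
        "nonbinder_major": _biased_weights(cfg, invert=True),
        "nonbinder_minor": _biased_weights(cfg, invert=False),
        "unassigned": np.ones(20),
    }


def sample_peptide(
    weights,
    length: int = PEPTIDE_LENGTH,
    rng: Optional[np.random.Generator] = None,
    position_overrides: Optional[Dict[int, np.ndarray]] = None,
) -> str:
    """Draw one peptide with i.i.d. residues from normalized *weights*,
    optionally replacing the weights at specific (0-based) positions."""
    rng = rng if rng is not None else np.random.default_rng()
    w = _as_weight_array(weights)
    alphabet = np.array(list(AMINO_ACIDS))
    chars = rng.choice(alphabet, size=length, p=w / w.sum())
    if position_overrides:
        for pos, ow in position_overrides.items():
            ow = _as_weight_array(ow)
            chars[pos] = rng.choice(alphabet, p=ow / ow.sum())
    return "".join(chars)


def _as_weight_array(weights) -> np.ndarray:
    if isinstance(weights, dict):
        w = np.array([weights.get(aa, 1.0) for aa in AMINO_ACIDS], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (20,) or np.any(w <= 0):
        raise ConfigurationError("weights must be 20 positive numbers")
    return w


def _sample_block(
    n: int,
    base_w: np.ndarray,
    rng: np.random.Generator,
    length: int,
    overrides: Optional[Dict[int, np.ndarray]] = None,
) -> list:
    if n == 0:
        return []
    p = base_w / base_w.sum()
    codes = rng.choice(20, size=(n, length), p=p)
    if overrides:
        for pos, ow in overrides.items():
            po = ow / ow.sum()
            codes[:, pos] = rng.choice(20, size=n, p=po)
    return ["".join(AMINO_ACIDS[c] for c in row) for row in codes]


def _position_overrides(
    cfg: SyntheticConfig, for_binders: bool
) -> Optional[Dict[int, np.ndarray]]:
    pe = cfg.position_effect
    if pe is None:
        return None
    residues = pe.residues if for_binders else tuple(reversed(pe.residues))
    overrides = {}
    for pos, res in zip(pe.positions, residues):
        w = np.ones(20)
        w[AA_INDEX[res]] *= pe.weight
        overrides[pos] = w
    return overrides


def generate_dataset(cfg: SyntheticConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a chip table and the matching ground-truth table.

    The chip table has the columns the chip reader expects (``peptide_id``,
    ``sequence``, ``source``, ``ivig_1..3``, ``sec_1..3``, ``experiment_id``);
    the truth table records the intended class, the composition
    subpopulation, and whether the row is a secondary-antibody artifact.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_peptides
    n_unassigned = round(n * cfg.unassigned_fraction)
    n_assignable = n - n_unassigned
    n_binders = round(n_assignable * cfg.binder_fraction)
    n_nonbinders = n_assignable - n_binders
    n_type2 = round(n_binders * cfg.type2_fraction)
    n_type1 = n_binders - n_type2
    n_nb_minor = round(n_nonbinders * cfg.nonbinder_minority_fraction)
    n_nb_major = n_nonbinders - n_nb_minor

    weights = subpopulation_weights(cfg)
    blocks = [
        ("type_I", "binding", n_type1, True),
        ("type_II", "binding", n_type2, True),
        ("nonbinder_major", "non-binding", n_nb_major, False),
        ("nonbinder_minor", "non-binding", n_nb_minor, False),
        ("unassigned", "unassigned", n_unassigned, False),
    ]
    sequences, subpops, classes = [], [], []
    for subpop, cls, count, is_binder in blocks:
        overrides = (
            _position_overrides(cfg, for_binders=is_binder)
            if cls != "unassigned" else None
        )
        sequences.extend(_sample_block(count, weights[subpop], rng, cfg.length, overrides))
        subpops.extend([subpop] * count)
        classes.extend([cls] * count)

    net = np.empty(len(sequences))
    for i, cls in enumerate(classes):
        if cls == "binding":
            med, sig = cfg.binder_median, cfg.binder_sigma
        elif cls == "non-binding":
            med, sig = cfg.nonbinder_median, cfg.nonbinder_sigma
        else:
            med, sig = cfg.unassigned_median, cfg.unassigned_sigma
        net[i] = rng.lognormal(mean=np.log(med), sigma=sig)
    secondary = rng.lognormal(
        mean=np.log(cfg.secondary_median), sigma=cfg.secondary_sigma, size=len(sequences)
    )
    ivig = net + secondary

    artifact = np.zeros(len(sequences), dtype=bool)
    n_artifacts = round(len(sequences) * cfg.secondary_artifact_rate)
    if n_artifacts:
        chosen = rng.choice(len(sequences), size=n_artifacts, replace=False)
        artifact[chosen] = True
        secondary[chosen] = ivig[chosen] * rng.uniform(1.2, 2.5, size=n_artifacts)

    order = rng.permutation(len(sequences))
    rows = []
    truth_rows = []
    for new_id, i in enumerate(order):
        pid = f"syn{new_id:06d}"
        ivig_reps = _replicates(ivig[i], cfg, rng)
        sec_reps = _replicates(secondary[i], cfg, rng)
        rows.append(
            (pid, sequences[i], "synthetic", *ivig_reps, *sec_reps, "synthetic-1")
        )
        truth_rows.append((pid, sequences[i], classes[i], subpops[i], bool(artifact[i])))
    rep_cols = [f"ivig_{k}" for k in range(1, cfg.n_replicates + 1)] + [
        f"sec_{k}" for k in range(1, cfg.n_replicates + 1)
    ]
    chip = pd.DataFrame(
        rows, columns=["peptide_id", "sequence", "source", *rep_cols, "experiment_id"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["peptide_id", "sequence", "true_class", "subpopulation", "artifact"],
    )
    return chip, truth


def _replicates(mean: float, cfg: SyntheticConfig, rng: np.random.Generator):
    reps = mean * (1.0 + cfg.replicate_cv * rng.standard_normal(cfg.n_replicates))
    return [int(round(min(max(v, 0.0), 65535.0))) for v in reps]


def write_dataset(cfg: SyntheticConfig, chip_path, truth_path) -> None:
    chip, truth = generate_dataset(cfg)
    chip.to_csv(chip_path, sep="\t", index=False)
    truth.to_csv(truth_path, sep="\t", index=False)


def position_effect_config(
    n_peptides: int,
    seed: int = 0,
    positions: Tuple[int, ...] = (2, 8),
    residues: Tuple[str, ...] = ("Y", "E"),
    weight: float = 20.0,
) -> SyntheticConfig:
    """Conditions isolating position-specific signal: unbiased composition,
    class-swapped positional preferences (default at peptide positions 3 and
    9, 1-based), no unassigned band or artifacts."""
    return SyntheticConfig(
        n_peptides=n_peptides,
        seed=seed,
        enrich_weight=1.0,
        deplete_weight=1.0,
        unassigned_fraction=0.0,
        secondary_artifact_rate=0.0,
        position_effect=PositionEffect(positions=positions, residues=residues, weight=weight),
    )
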