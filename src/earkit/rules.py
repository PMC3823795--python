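"""Interpretable classification: ordered-rule induction and logistic regression.

Rule induction follows the RIPPER recipe (sequential covering for the
minority *binding* class with non-binding as default): the still-uncovered
examples are split 2:1 into a grow and a prune set; a rule is grown by
greedily adding the condition ``attribute < v`` or ``attribute >= v`` with
the best FOIL information gain until it covers no grow-set negatives, then
pruned back by maximizing (p - n)/(p + n) on the prune set.  Rule addition
stops when a pruned rule is wrong more often than right on the prune set or
when the description length of the rule list exceeds the best one seen by a
bit budget (default 64 bits).  An optional optimization pass re-grows each
rule as a replacement and a revision and keeps whichever variant gives the
lowest training error of the whole ordered list.

Evaluation is strictly ordered: the first matching rule wins, otherwise the
default class applies.  Rule summaries report, per attribute occurring in any
rule, whether binding requires a low or a high value and the percentage of
all binding peptides correctly classified by the rules containing that
attribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, InputError
from .features import FeatureMatrix
from .peptide_io import BINDING, NON_BINDING


@dataclass(frozen=True)
class Conjunct:
    attribute: str
    comparator: str  # "<" or ">="
    value: float

    def __post_init__(self) -> None:
        if self.comparator not in ("<", ">="):
            raise ConfigurationError(f"comparator must be '<' or '>=', got {self.comparator!r}")

    def __str__(self) -> str:
        return f"({self.attribute} {self.comparator} {self.value:.6g})"


@dataclass(frozen=True)
class Rule:
    """A conjunction of attribute comparisons predicting the binding class."""

    conjuncts: Tuple[Conjunct, ...]
    predicted_class: str = BINDING

    def __post_init__(self) -> None:
        if not self.conjuncts:
            raise ConfigurationError("a rule needs at least one conjunct")

    def covers(self, values: np.ndarray, attr_index: dict) -> np.ndarray:
        mask = np.ones(values.shape[0], dtype=bool)
        for c in self.conjuncts:
            col = values[:, attr_index[c.attribute]]
            mask &= (col < c.value) if c.comparator == "<" else (col >= c.value)
        return mask

    def __str__(self) -> str:
        return "IF " + " AND ".join(str(c) for c in self.conjuncts) + f" THEN class = {self.predicted_class}"


@dataclass
class RuleSet:
    """An ordered rule list with a default class; first matching rule wins."""

    rules: List[Rule]
    attribute_names: List[str]
    default_class: str = NON_BINDING

    @property
    def n_comparisons(self) -> int:
        return sum(len(r.conjuncts) for r in self.rules)

    def _attr_index(self) -> dict:
        return {a: i for i, a in enumerate(self.attribute_names)}

    def first_match(self, values: np.ndarray) -> np.ndarray:
        """Index of the first matching rule per row (-1 = default)."""
        idx = self._attr_index()
        out = np.full(values.shape[0], -1, dtype=int)
        unresolved = np.ones(values.shape[0], dtype=bool)
        for r_no, rule in enumerate(self.rules):
            hit = unresolved & rule.covers(values, idx)
            out[hit] = r_no
            unresolved &= ~hit
        return out

    def predict(self, features) -> List[str]:
        values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
        match = self.first_match(values)
        return [
            self.rules[m].predicted_class if m >= 0 else self.default_class
            for m in match
        ]

    def to_text(self) -> str:
        lines = [str(r).replace("IF", "IF", 1) for r in self.rules]
        body = "\nELSE ".join(lines) if lines else ""
        tail = f"ELSE class = {self.default_class}"
        return (body + "\n" + tail) if body else tail

    def to_json_dict(self) -> dict:
        return {
            "rules": [
                {
                    "conjuncts": [
                        {"attribute": c.attribute, "comparator": c.comparator, "value": c.value}
                        for c in r.conjuncts
                    ],
                    "predicted_class": r.predicted_class,
                }
                for r in self.rules
            ],
            "default_class": self.default_class,
        }


@dataclass
class RuleSummaryRow:
    attribute: str
    direction: str  # "low" or "high"
    pct_correct: float


def _candidate_thresholds(col: np.ndarray, max_thresholds: int) -> np.ndarray:
    uniq = np.unique(col)
    if len(uniq) < 2:
        return np.empty(0)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    if len(cuts) > max_thresholds:
        pick = np.linspace(0, len(cuts) - 1, max_thresholds).round().astype(int)
        cuts = cuts[np.unique(pick)]
    return cuts


def _foil_gain(p0: int, n0: int, p1: int, n1: int) -> float:
    if p1 == 0:
        return -np.inf
    return p1 * (np.log2(p1 / (p1 + n1)) - np.log2(p0 / (p0 + n0)))


def _grow_rule(
    X: np.ndarray,
    y: np.ndarray,
    attr_names: Sequence[str],
    max_thresholds: int,
    start: Tuple[Conjunct, ...] = (),
    attr_index: Optional[dict] = None,
) -> Tuple[Conjunct, ...]:
    """Greedily add conditions by FOIL gain until no grow-set negative is covered."""
    attr_index = attr_index or {a: i for i, a in enumerate(attr_names)}
    conjuncts = list(start)
    covered = np.ones(len(y), dtype=bool)
    for c in conjuncts:
        col = X[:, attr_index[c.attribute]]
        covered &= (col < c.value) if c.comparator == "<" else (col >= c.value)
    while True:
        p0 = int(np.sum(y[covered] == 1))
        n0 = int(np.sum(y[covered] == 0))
        if n0 == 0 or p0 == 0:
            break
        best = None  # (gain, attr_no, op, threshold, new_mask)
        cov_idx = np.flatnonzero(covered)
        Xc = X[cov_idx]
        yc = y[cov_idx]
        for a in range(X.shape[1]):
            col = Xc[:, a]
            cuts = _candidate_thresholds(col, max_thresholds)
            if len(cuts) == 0:
                continue
            ge = col[:, None] >= cuts[None, :]
            pos = yc == 1
            p_ge = (ge & pos[:, None]).sum(axis=0)
            n_ge = (ge & ~pos[:, None]).sum(axis=0)
            p_lt = pos.sum() - p_ge
            n_lt = (~pos).sum() - n_ge
            for t_no, t in enumerate(cuts):
                for op, p1, n1 in ((">=", p_ge[t_no], n_ge[t_no]), ("<", p_lt[t_no], n_lt[t_no])):
                    gain = _foil_gain(p0, n0, int(p1), int(n1))
                    key = (gain, -a, op, -t)
                    if np.isfinite(gain) and gain > 0 and (best is None or key > best[0]):
                        best = (key, a, op, float(t))
        if best is None:
            break
        _, a, op, t = best
        conjuncts.append(Conjunct(attr_names[a], op, t))
        col = X[:, a]
        covered &= (col < t) if op == "<" else (col >= t)
    return tuple(conjuncts)


def _prune_value(conjuncts: Tuple[Conjunct, ...], X: np.ndarray, y: np.ndarray, attr_index: dict) -> float:
    mask = np.ones(len(y), dtype=bool)
    for c in conjuncts:
        col = X[:, attr_index[c.attribute]]
        mask &= (col < c.value) if c.comparator == "<" else (col >= c.value)
    p = int(np.sum(y[mask] == 1))
    n = int(np.sum(y[mask] == 0))
    if p + n == 0:
        return -1.0
    return (p - n) / (p + n)


def _prune_rule(
    conjuncts: Tuple[Conjunct, ...], X: np.ndarray, y: np.ndarray, attr_index: dict
) -> Tuple[Conjunct, ...]:
    """Drop a final sequence of conjuncts maximizing (p-n)/(p+n) on the prune set."""
    best_k, best_v = len(conjuncts), _prune_value(conjuncts, X, y, attr_index)
    for k in range(len(conjuncts) - 1, 0, -1):
        v = _prune_value(conjuncts[:k], X, y, attr_index)
        if v >= best_v:  # prefer shorter on ties
            best_k, best_v = k, v
    return conjuncts[:best_k]


def _log2_choose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return 0.0
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / np.log(2.0)


def _ruleset_bits(
    rules: Sequence[Rule], X: np.ndarray, y: np.ndarray, attr_names: Sequence[str], max_thresholds: int
) -> float:
    """Simplified MDL: rule-encoding bits plus exception-coding bits."""
    attr_index = {a: i for i, a in enumerate(attr_names)}
    n_conditions = max(2 * X.shape[1] * max_thresholds, 2)
    theory = 0.0
    for r in rules:
        k = len(r.conjuncts)
        theory += 0.5 * (np.log2(k + 1) + k * np.log2(n_conditions))
    covered = np.zeros(len(y), dtype=bool)
    for r in rules:
        covered |= r.covers(X, attr_index)
    fp = int(np.sum(covered & (y == 0)))
    fn = int(np.sum(~covered & (y == 1)))
    n_cov, n_uncov = int(covered.sum()), int((~covered).sum())
    exceptions = _log2_choose(n_cov, fp) + _log2_choose(n_uncov, fn)
    return theory + exceptions


def _grow_prune_split(
    idx: np.ndarray, y: np.ndarray, grow_fraction: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    grow, prune = [], []
    for cls in (0, 1):
        cls_idx = idx[y[idx] == cls]
        perm = rng.permutation(cls_idx)
        cut = max(1, int(round(len(perm) * grow_fraction))) if len(perm) else 0
        grow.extend(perm[:cut])
        prune.extend(perm[cut:])
    return np.array(sorted(grow), dtype=int), np.array(sorted(prune), dtype=int)


def induce_rules(
    features: FeatureMatrix,
    labels: Sequence[str],
    seed: int = 0,
    grow_fraction: float = 2.0 / 3.0,
    mdl_budget: float = 64.0,
    optimize_passes: int = 1,
    max_thresholds: int = 24,
    max_rules: int = 64,
) -> RuleSet:
    """Induce an ordered rule list for the binding class (sequential covering)."""
    X = features.values
    attr_names = list(features.attribute_names)
    attr_index = {a: i for i, a in enumerate(attr_names)}
    y = np.array([1 if l == BINDING else 0 for l in labels])
    if y.min() == y.max():
        raise InputError("rule induction requires both classes")
    rng = np.random.default_rng(seed)

    rules: List[Rule] = []
    remaining = np.arange(len(y))
    min_bits = _ruleset_bits([], X, y, attr_names, max_thresholds)
    while len(rules) < max_rules and np.any(y[remaining] == 1):
        if np.all(y[remaining] == 1):
            break  # only positives left: they fall to the default (no signal to grow on)
        grow_idx, prune_idx = _grow_prune_split(remaining, y, grow_fraction, rng)
        grown = _grow_rule(X[grow_idx], y[grow_idx], attr_names, max_thresholds, attr_index=attr_index)
        if not grown:
            break
        if len(prune_idx):
            pruned = _prune_rule(grown, X[prune_idx], y[prune_idx], attr_index)
            if _prune_value(pruned, X[prune_idx], y[prune_idx], attr_index) < 0:
                break  # pruned rule wrong more often than right
        else:
            pruned = grown
        rule = Rule(conjuncts=pruned)
        rules.append(rule)
        bits = _ruleset_bits(rules, X, y, attr_names, max_thresholds)
        if bits > min_bits + mdl_budget:
            rules.pop()
            break
        min_bits = min(min_bits, bits)
        covered = rule.covers(X, attr_index)
        remaining = remaining[~covered[remaining]]

    for _ in range(max(0, optimize_passes)):
        rules = _optimize(rules, X, y, attr_names, attr_index, grow_fraction, max_thresholds, rng)

    # drop rules that correctly fire for no positive example in ordered context
    ruleset = RuleSet(rules=rules, attribute_names=attr_names)
    match = ruleset.first_match(X)
    useful = [i for i in range(len(rules)) if np.any((match == i) & (y == 1))]
    ruleset.rules = [rules[i] for i in useful]
    return ruleset


def _ordered_errors(rules: List[Rule], X: np.ndarray, y: np.ndarray, attr_names: List[str]) -> int:
    rs = RuleSet(rules=rules, attribute_names=attr_names) if rules else None
    if rs is None:
        return int(np.sum(y == 1))
    pred = np.array([1 if l == BINDING else 0 for l in rs.predict(X)])
    return int(np.sum(pred != y))


def _optimize(
    rules: List[Rule],
    X: np.ndarray,
    y: np.ndarray,
    attr_names: List[str],
    attr_index: dict,
    grow_fraction: float,
    max_thresholds: int,
    rng: np.random.Generator,
) -> List[Rule]:
    """One RIPPER optimization pass: per rule, try a re-grown replacement and a
    grown-on revision; keep the variant with the fewest ordered-list errors."""
    out = list(rules)
    for i in range(len(out)):
        others = out[:i] + out[i + 1 :]
        covered_by_others = np.zeros(len(y), dtype=bool)
        for r in others:
            covered_by_others |= r.covers(X, attr_index)
        idx = np.flatnonzero(~covered_by_others)
        if len(idx) == 0 or len(np.unique(y[idx])) < 2:
            continue
        grow_idx, prune_idx = _grow_prune_split(idx, y, grow_fraction, rng)
        variants = [out[i]]
        repl = _grow_rule(X[grow_idx], y[grow_idx], attr_names, max_thresholds, attr_index=attr_index)
        if repl:
            if len(prune_idx):
                repl = _prune_rule(repl, X[prune_idx], y[prune_idx], attr_index)
            variants.append(Rule(conjuncts=repl))
        revis = _grow_rule(
            X[grow_idx], y[grow_idx], attr_names, max_thresholds,
            start=out[i].conjuncts, attr_index=attr_index,
        )
        if revis and revis != out[i].conjuncts:
            if len(prune_idx):
                revis = _prune_rule(revis, X[prune_idx], y[prune_idx], attr_index)
            variants.append(Rule(conjuncts=revis))
        errors = [
            _ordered_errors(out[:i] + [v] + out[i + 1 :], X, y, attr_names)
            for v in variants
        ]
        out[i] = variants[int(np.argmin(errors))]
    return out


def summarize_rules(
    ruleset: RuleSet, features: FeatureMatrix, labels: Sequence[str]
) -> List[RuleSummaryRow]:
    """One summary row per attribute occurring in any rule.

    ``pct_correct`` is the percentage of all binding peptides whose first
    matching rule predicts binding and contains the attribute (ordered,
    in-context evaluation).  ``direction`` is the comparison sense required
    for the binding class ("high" for >=, "low" for <).  Within one rule an
    attribute votes once, with the sense of its first conjunct: a later
    opposite-sense conjunct on the same attribute only refines an interval.
    Across rules the sense covering more correctly classified binders wins.
    """
    for r in ruleset.rules:
        for c in r.conjuncts:
            if c.attribute not in features.attribute_names:
                raise InputError(f"attribute {c.attribute!r} absent from feature matrix")
    y = np.array([1 if l == BINDING else 0 for l in labels])
    match = ruleset.first_match(features.values)
    n_binding = int(np.sum(y == 1))
    if n_binding == 0:
        raise InputError("no binding peptides to summarize against")
    correct_binders_by_rule = [
        np.flatnonzero((match == i) & (y == 1)) for i in range(len(ruleset.rules))
    ]
    stats: dict = {}
    for i, rule in enumerate(ruleset.rules):
        n_correct = len(correct_binders_by_rule[i])
        seen_in_rule = set()
        for c in rule.conjuncts:
            entry = stats.setdefault(c.attribute, {"high": 0.0, "low": 0.0, "covered": set()})
            if c.attribute not in seen_in_rule:
                entry["high" if c.comparator == ">=" else "low"] += n_correct
                seen_in_rule.add(c.attribute)
            entry["covered"].update(correct_binders_by_rule[i].tolist())
    rows = []
    for attribute, entry in stats.items():
        direction = "high" if entry["high"] >= entry["low"] else "low"
        pct = 100.0 * len(entry["covered"]) / n_binding
        rows.append(RuleSummaryRow(attribute=attribute, direction=direction, pct_correct=pct))
    rows.sort(key=lambda r: (-r.pct_correct, r.attribute))
    return rows


@dataclass
class InterpretableClassifier:
    """Regularized logistic regression over interpretable attributes."""

    attribute_names: List[str]
    kept_columns: np.ndarray
    pipeline: object

    def predict_proba_binding(self, features) -> np.ndarray:
        values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
        proba = self.pipeline.predict_proba(values[:, self.kept_columns])
        classes = list(self.pipeline.classes_)
        return proba[:, classes.index(1)]

    def predict(self, features, cutoff: float = 0.5) -> List[str]:
        p = self.predict_proba_binding(features)
        return [BINDING if v > cutoff else NON_BINDING for v in p]


def fit_interpretable_classifier(
    features: FeatureMatrix, labels: Sequence[str], seed: int = 0, C: float = 1.0
) -> InterpretableClassifier:
    """Fit the logistic model used by ML-simple and the stratification steps.

    Constant attribute columns are dropped with a warning; coefficients stay
    finite through L2 regularization.
    """
    y = np.array([1 if l == BINDING else 0 for l in labels])
    if y.min() == y.max():
        raise InputError("classifier fitting requires both classes")
    X = features.values
    variable = X.std(axis=0) > 0
    if not variable.all():
        n_dropped = int((~variable).sum())
        warnings.warn(f"dropping {n_dropped} constant attribute column(s)", stacklevel=2)
    kept = np.flatnonzero(variable)
    pipe = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000, C=C))
    pipe.fit(X[:, kept], y)
    return InterpretableClassifier(
        attribute_names=list(features.attribute_names),
        kept_columns=kept,
        pipeline=pipe,
    )
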