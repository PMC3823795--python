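"""Rule induction, ordered evaluation, summaries, interpretable classifier."""

import numpy as np
import pytest

from earkit import rules as ru
from earkit.errors import InputError
from earkit.features import FeatureMatrix, interpretable_feature_matrix

from conftest import toy_separable_peptides


def matrix_from(peps, k_max=1):
    return (
        interpretable_feature_matrix([(p.peptide_id, p.sequence) for p in peps], k_max=k_max),
        [p.label for p in peps],
    )


class TestInduceRules:
    def test_threshold_separable_data_gives_single_conjunct_rule(self):
        peps = toy_separable_peptides(n_per_class=30, seed=1)
        feats, labels = matrix_from(peps)
        rs = ru.induce_rules(feats, labels, seed=0)
        assert len(rs.rules) == 1
        assert len(rs.rules[0].conjuncts) == 1
        assert rs.default_class == "non-binding"
        assert rs.predict(feats) == labels

    def test_rules_reference_only_present_attributes(self):
        peps = toy_separable_peptides(n_per_class=25, seed=2)
        feats, labels = matrix_from(peps)
        rs = ru.induce_rules(feats, labels, seed=0)
        for rule in rs.rules:
            for c in rule.conjuncts:
                assert c.attribute in feats.attribute_names

    def test_coverage_matches_brute_force_on_toy_set(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("AYEW"), size=15)) for _ in range(20)]
        labels = ["binding" if s.count("Y") + s.count("W") >= 6 else "non-binding" for s in seqs]
        feats = interpretable_feature_matrix([(f"p{i}", s) for i, s in enumerate(seqs)])
        rs = ru.induce_rules(feats, labels, seed=3)

        def brute_force_predict(row):
            for rule in rs.rules:
                ok = True
                for c in rule.conjuncts:
                    v = row[feats.attribute_names.index(c.attribute)]
                    ok &= (v < c.value) if c.comparator == "<" else (v >= c.value)
                if ok:
                    return rule.predicted_class
            return rs.default_class

        expected = [brute_force_predict(feats.values[i]) for i in range(20)]
        assert rs.predict(feats) == expected

    def test_single_class_input_rejected(self):
        peps = toy_separable_peptides(n_per_class=10)
        binders = [p for p in peps if p.label == "binding"]
        feats, labels = matrix_from(binders)
        with pytest.raises(InputError):
            ru.induce_rules(feats, labels, seed=0)

    def test_deterministic_given_seed(self):
        peps = toy_separable_peptides(n_per_class=25, seed=6)
        feats, labels = matrix_from(peps)
        a = ru.induce_rules(feats, labels, seed=9)
        b = ru.induce_rules(feats, labels, seed=9)
        assert a.to_text() == b.to_text()


class TestOrderedEvaluation:
    def _two_rule_set(self):
        names = ["x", "y"]
        r1 = ru.Rule(conjuncts=(ru.Conjunct("x", ">=", 0.5),))
        r2 = ru.Rule(conjuncts=(ru.Conjunct("y", ">=", 0.5),))
        return names, r1, r2

    def test_first_match_attribution_depends_on_order(self):
        names, r1, r2 = self._two_rule_set()
        values = np.array([[1.0, 1.0]])  # matches both rules
        fwd = ru.RuleSet(rules=[r1, r2], attribute_names=names)
        rev = ru.RuleSet(rules=[r2, r1], attribute_names=names)
        assert fwd.first_match(values)[0] == 0
        assert rev.first_match(values)[0] == 0  # different rule object wins
        assert fwd.rules[0] is r1 and rev.rules[0] is r2

    def test_summary_attribution_changes_under_permutation(self):
        names, r1, r2 = self._two_rule_set()
        values = np.array([[1.0, 1.0], [0.0, 1.0]])
        feats = FeatureMatrix(["a", "b"], names, values)
        labels = ["binding", "binding"]
        fwd = ru.RuleSet(rules=[r1, r2], attribute_names=names)
        rev = ru.RuleSet(rules=[r2, r1], attribute_names=names)
        pct = lambda rows, attr: {r.attribute: r.pct_correct for r in rows}[attr]
        rows_fwd = ru.summarize_rules(fwd, feats, labels)
        rows_rev = ru.summarize_rules(rev, feats, labels)
        # under fwd order, rule on x catches peptide "a"; under rev order rule on y does
        assert pct(rows_fwd, "x") == pytest.approx(50.0)
        assert pct(rows_rev, "y") == pytest.approx(100.0)


class TestSummaries:
    def test_percentage_arithmetic(self):
        # rules containing "x" correctly classify 7 of 13 binders -> 53.8%
        names = ["x"]
        rule = ru.Rule(conjuncts=(ru.Conjunct("x", ">=", 0.5),))
        rs = ru.RuleSet(rules=[rule], attribute_names=names)
        values = np.array([[1.0]] * 7 + [[0.0]] * 6 + [[0.0]] * 5)
        labels = ["binding"] * 13 + ["non-binding"] * 5
        feats = FeatureMatrix([f"p{i}" for i in range(18)], names, values)
        (row,) = ru.summarize_rules(rs, feats, labels)
        assert row.attribute == "x"
        assert row.direction == "high"
        assert row.pct_correct == pytest.approx(100 * 7 / 13)

    def test_attribute_in_no_rule_gets_no_row(self):
        peps = toy_separable_peptides(n_per_class=20, seed=7)
        feats, labels = matrix_from(peps)
        rs = ru.induce_rules(feats, labels, seed=0)
        used = {c.attribute for r in rs.rules for c in r.conjuncts}
        rows = ru.summarize_rules(rs, feats, labels)
        assert {r.attribute for r in rows} == used

    def test_absent_attribute_is_consistency_error(self):
        rule = ru.Rule(conjuncts=(ru.Conjunct("missing", ">=", 0.5),))
        rs = ru.RuleSet(rules=[rule], attribute_names=["missing"])
        feats = FeatureMatrix(["a"], ["other"], np.zeros((1, 1)))
        with pytest.raises(InputError):
            ru.summarize_rules(rs, feats, ["binding"])

    def test_text_serialization_has_paper_shape(self):
        rule = ru.Rule(conjuncts=(ru.Conjunct("aromaticity", ">=", 0.2), ru.Conjunct("polarity", "<", 8.0)))
        rs = ru.RuleSet(rules=[rule], attribute_names=["aromaticity", "polarity"])
        text = rs.to_text()
        assert text.startswith("IF (aromaticity >= 0.2) AND (polarity < 8) THEN class = binding")
        assert text.endswith("ELSE class = non-binding")


class TestInterpretableClassifier:
    def test_separable_training_accuracy(self):
        peps = toy_separable_peptides(n_per_class=25, seed=3)
        feats, labels = matrix_from(peps)
        with pytest.warns(UserWarning):  # constant k-mer columns dropped
            clf = ru.fit_interpretable_classifier(feats, labels, seed=0)
        assert clf.predict(feats) == labels

    def test_probability_monotone_in_linear_score(self):
        peps = toy_separable_peptides(n_per_class=25, seed=3)
        feats, labels = matrix_from(peps)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = ru.fit_interpretable_classifier(feats, labels, seed=0)
        lr = clf.pipeline.named_steps["logisticregression"]
        scaler = clf.pipeline.named_steps["standardscaler"]
        X = scaler.transform(feats.values[:, clf.kept_columns])
        z = X @ lr.coef_.ravel() + lr.intercept_[0]
        p = clf.predict_proba_binding(feats)
        order = np.argsort(z)
        assert np.all(np.diff(p[order]) >= -1e-12)

    def test_cross_validated_accuracy_above_0_9_on_type_I_only_data(self):
        from conftest import assignable_from_chip

        from earkit.stratify import groupwise_cv_performance
        from earkit.synthetic import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(
            n_peptides=2000, seed=4, type2_fraction=0.0, nonbinder_minority_fraction=0.0
        )
        chip, _ = generate_dataset(cfg)
        peps = assignable_from_chip(chip)
        feats, labels = matrix_from(peps)
        acc, _ = groupwise_cv_performance(feats, labels, folds=10, seed=4)
        assert acc > 0.9

    def test_single_class_rejected(self):
        peps = [p for p in toy_separable_peptides(10) if p.label == "binding"]
        feats, labels = matrix_from(peps)
        with pytest.raises(InputError):
            ru.fit_interpretable_classifier(feats, labels)
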