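"""Classifiability partitioning, degree iteration, PWM rescue, EAR types."""

import numpy as np
import pytest

from earkit import stratify as st
from earkit.errors import EarError, InputError
from earkit.features import interpretable_feature_matrix
from earkit.pwm import RatioPWM
from earkit.stratify import (
    assign_ear_types,
    iterate_partition,
    partition_by_classifiability,
    pwm_rescue,
    scatter_coordinates,
    stratify_peptides,
)

from conftest import toy_separable_peptides


def matrix_and_labels(peps, k_max=1):
    feats = interpretable_feature_matrix([(p.peptide_id, p.sequence) for p in peps], k_max=k_max)
    return feats, [p.label for p in peps]


@pytest.fixture(scope="module")
def default_partition(assignable_peptides):
    part, types, feats = stratify_peptides(assignable_peptides, seed=5)
    return part, types, feats


class TestPartition:
    def test_separable_data_gives_empty_unclassifiable_set(self):
        peps = toy_separable_peptides(n_per_class=30, seed=0)
        feats, labels = matrix_and_labels(peps)
        part = partition_by_classifiability(feats, labels, seed=1)
        assert part.unclassifiable_ids == []
        assert sorted(part.classifiable_ids) == sorted(feats.peptide_ids)

    def test_label_inverting_classifier_gives_empty_classifiable_set(self, monkeypatch):
        peps = toy_separable_peptides(n_per_class=30, seed=0)
        feats, labels = matrix_and_labels(peps)

        class Inverter:
            """Judge that always predicts the wrong class for the toy data:
            poly-Y binders called non-binding and vice versa."""

            def predict(self, features, cutoff=0.5):
                col = features.attribute_names.index("aromaticity")
                return [
                    "non-binding" if v > 0.5 else "binding"
                    for v in features.values[:, col]
                ]

        monkeypatch.setattr(
            st, "fit_interpretable_classifier", lambda *a, **k: Inverter()
        )
        part = partition_by_classifiability(feats, labels, seed=1)
        assert part.classifiable_ids == []
        assert sorted(part.unclassifiable_ids) == sorted(feats.peptide_ids)

    def test_partition_is_disjoint_cover(self, default_partition, assignable_peptides):
        part, _, _ = default_partition
        all_ids = {p.peptide_id for p in assignable_peptides}
        assert set(part.classifiable_ids) | set(part.unclassifiable_ids) == all_ids
        assert set(part.classifiable_ids).isdisjoint(part.unclassifiable_ids)

    def test_majority_of_type_II_binders_unclassifiable(
        self, default_partition, truth_by_id, assignable_peptides
    ):
        part, _, _ = default_partition
        uncl = set(part.unclassifiable_ids)
        t2 = [
            p.peptide_id
            for p in assignable_peptides
            if truth_by_id.loc[p.peptide_id].subpopulation == "type_II"
        ]
        assert np.mean([pid in uncl for pid in t2]) > 0.5

    def test_same_seed_reproduces_partition(self, assignable_peptides):
        a, _, _ = stratify_peptides(assignable_peptides, seed=5)
        b, _, _ = stratify_peptides(assignable_peptides, seed=5)
        assert a.classifiable_ids == b.classifiable_ids
        assert a.unclassifiable_ids == b.unclassifiable_ids


class TestIteration:
    def test_second_degree_nests_inside_first(self, default_partition, assignable_peptides):
        part, _, feats = default_partition
        labels = [p.label for p in assignable_peptides]
        second = iterate_partition(feats, labels, part, seed=6)
        first_unclass = set(part.unclassifiable_ids)
        assert set(second.classifiable_ids) <= first_unclass
        assert set(second.unclassifiable_ids) <= first_unclass
        assert second.degree == 2

    def test_groupwise_cv_beats_whole_set_on_unclassifiable_peptides(
        self, default_partition, assignable_peptides
    ):
        """Within-group retraining resolves the contradiction that the
        whole-set classifier faces on the unclassifiable peptides."""
        part, _, feats = default_partition
        labels = [p.label for p in assignable_peptides]
        # whole-set classifier accuracy measured on the unclassifiable peptides is
        # 0 by construction (they are exactly the misclassified ones)...
        acc_in_group, auc_in_group = st.groupwise_cv_performance(
            feats, labels, ids=part.unclassifiable_ids, folds=10, seed=6
        )
        assert acc_in_group > 0.85
        assert auc_in_group > 0.85


class TestPWMRescue:
    def test_position_only_signal_recovered(self, position_effect_peptides):
        res = pwm_rescue(position_effect_peptides)
        assert res.roc.auc > 0.9

    def test_composition_classifier_blind_to_position_signal(self, position_effect_peptides):
        feats, labels = matrix_and_labels(position_effect_peptides)
        _, auc = st.groupwise_cv_performance(feats, labels, folds=10, seed=9)
        assert abs(auc - 0.5) < 0.1

    def test_third_degree_sets_partition_the_input(self, position_effect_peptides):
        res = pwm_rescue(position_effect_peptides)
        all_ids = {p.peptide_id for p in position_effect_peptides}
        assert set(res.classifiable_ids) | set(res.unclassifiable_ids) == all_ids
        assert set(res.classifiable_ids).isdisjoint(res.unclassifiable_ids)

    def test_disjoint_position_usage_is_perfectly_separable(self):
        from conftest import make_labeled

        binders = make_labeled(["AY" + "G" * 13, "AY" + "G" * 12 + "A"], "binding")
        nonbinders = make_labeled(["CW" + "G" * 13, "CW" + "G" * 12 + "A"], "non-binding", start=2)
        res = pwm_rescue(binders + nonbinders)
        assert res.roc.auc == pytest.approx(1.0)
        assert res.unclassifiable_ids == []

    def test_single_class_rejected(self):
        from conftest import make_labeled

        with pytest.raises(EarError):
            pwm_rescue(make_labeled(["A" * 15, "C" * 15], "binding"))


class TestEARTypes:
    def test_type_assignment_follows_definition(self, default_partition, assignable_peptides):
        part, types, _ = default_partition
        labels = {p.peptide_id: p.label for p in assignable_peptides}
        classifiable = set(part.classifiable_ids)
        for pid in types.type_I_ids:
            assert labels[pid] == "binding" and pid in classifiable
        for pid in types.type_II_ids:
            assert labels[pid] == "binding" and pid not in classifiable
        assert set(types.type_I_ids).isdisjoint(types.type_II_ids)

    def test_nonbinding_peptides_receive_no_type(self, default_partition, assignable_peptides):
        _, types, _ = default_partition
        nonbinding = {p.peptide_id for p in assignable_peptides if p.label == "non-binding"}
        assert nonbinding.isdisjoint(types.type_I_ids)
        assert nonbinding.isdisjoint(types.type_II_ids)

    def test_types_never_change_binding_labels(self, default_partition, assignable_peptides):
        _, types, _ = default_partition
        binding = {p.peptide_id for p in assignable_peptides if p.label == "binding"}
        assert set(types.type_I_ids) | set(types.type_II_ids) == binding

    def test_uncovered_peptide_is_consistency_error(self, default_partition):
        part, _, _ = default_partition
        with pytest.raises(InputError):
            assign_ear_types(part, {"not-a-peptide": "binding"})


class TestScatter:
    def test_all_ones_pwms_put_every_peptide_at_unit_point(self):
        ones = RatioPWM(ratios=np.ones((20, 15)), positional_propensity=np.ones(20))
        coords = scatter_coordinates([("a", "A" * 15), ("b", "ACDEFGHIKLMNPQR")], ones, ones)
        assert np.allclose(coords.x, 1.0) and np.allclose(coords.y, 1.0)

    def test_coordinates_equal_pwm_scores(self, rng):
        from earkit.pwm import PWMClassifier, pwm_score

        r1 = rng.uniform(0.5, 2.0, size=(20, 15))
        r2 = rng.uniform(0.5, 2.0, size=(20, 15))
        p1 = RatioPWM(ratios=r1, positional_propensity=r1.mean(axis=1))
        p2 = RatioPWM(ratios=r2, positional_propensity=r2.mean(axis=1))
        pep = ("a", "ACDEFGHIKLMNPQR")
        coords = scatter_coordinates([pep], p1, p2)
        assert coords.x[0] == pytest.approx(pwm_score(pep[1], PWMClassifier(p1))[0])
        assert coords.y[0] == pytest.approx(pwm_score(pep[1], PWMClassifier(p2))[0])

    def test_type_I_and_type_II_separate_along_x(
        self, default_partition, assignable_peptides
    ):
        from scipy.stats import mannwhitneyu

        from earkit.pwm import build_frequency_pwm, build_ratio_pwm, filter_to_length

        part, types, _ = default_partition
        by_id = {p.peptide_id: p.sequence for p in assignable_peptides}
        binding = [p.sequence for p in assignable_peptides if p.label == "binding"]
        nonbinding = [p.sequence for p in assignable_peptides if p.label == "non-binding"]
        pwm_all = build_ratio_pwm(
            build_frequency_pwm(binding), build_frequency_pwm(nonbinding)
        )
        label_by_id = {p.peptide_id: p.label for p in assignable_peptides}
        uncl = part.unclassifiable_ids
        uncl_b = [by_id[pid] for pid in uncl if label_by_id[pid] == "binding"]
        uncl_n = [by_id[pid] for pid in uncl if label_by_id[pid] == "non-binding"]
        pwm_uncl = build_ratio_pwm(
            build_frequency_pwm(uncl_b), build_frequency_pwm(uncl_n)
        )
        pep_pairs = [(pid, by_id[pid]) for pid in types.type_I_ids + types.type_II_ids]
        coords = scatter_coordinates(pep_pairs, pwm_all, pwm_uncl)
        n1 = len(types.type_I_ids)
        x1, x2 = coords.x[:n1], coords.x[n1:]
        stat = mannwhitneyu(x1, x2, alternative="greater")
        assert stat.pvalue < 1e-6  # Type I scores higher on the whole-set PWM
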