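"""Frequency/ratio PWMs, propensities, scoring and heat-map export."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earkit import pwm
from earkit.errors import ConfigurationError, InputError
from earkit.scales import AMINO_ACIDS

peptides_15 = st.text(alphabet=AMINO_ACIDS, min_size=15, max_size=15)


class TestFrequencyPWM:
    def test_homopolymer_without_smoothing(self):
        m = pwm.build_frequency_pwm(["A" * 15], pseudocount=0)
        assert np.all(m.frequencies[0] == 1.0)  # row A
        assert np.all(m.frequencies[1:] == 0.0)

    def test_closed_form_smoothing(self):
        m = pwm.build_frequency_pwm(["A" + "G" * 14, "C" + "G" * 14], pseudocount=1)
        assert m.frequency("A", 1) == pytest.approx((1 + 1) / (2 + 20))
        assert m.frequency("C", 1) == pytest.approx(2 / 22)
        assert m.frequency("W", 1) == pytest.approx(1 / 22)

    @given(st.lists(peptides_15, min_size=1, max_size=8))
    @settings(max_examples=25, deadline=None)
    def test_columns_sum_to_one(self, peps):
        m = pwm.build_frequency_pwm(peps)
        assert np.allclose(m.frequencies.sum(axis=0), 1.0, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            pwm.build_frequency_pwm(["AAA"])


class TestRatioPWM:
    def test_identical_sets_give_all_ones(self):
        peps = ["ACDEFGHIKLMNPQR", "YYYYYWWWWWFFFFF"]
        f = pwm.build_frequency_pwm(peps)
        r = pwm.build_ratio_pwm(f, f)
        assert np.allclose(r.ratios, 1.0)
        assert np.allclose(r.positional_propensity, 1.0)

    def test_toy_ratio_by_hand_arithmetic(self):
        b = pwm.build_frequency_pwm(["Y" + "G" * 14], pseudocount=1)
        n = pwm.build_frequency_pwm(["A" + "G" * 14], pseudocount=1)
        r = pwm.build_ratio_pwm(b, n)
        # binding: freq(Y,1) = (1+1)/(1+20) ; non-binding: freq(Y,1) = (0+1)/21
        assert r.ratio("Y", 1) == pytest.approx(2.0)
        assert r.ratio("A", 1) == pytest.approx(0.5)

    def test_enrichment_flags(self):
        ratios = np.ones((20, 15))
        ratios[0, 0] = 2.5
        ratios[1, 0] = 0.5
        r = pwm.RatioPWM(ratios=ratios, positional_propensity=ratios.mean(axis=1))
        assert r.enriched[0, 0] and not r.enriched[1, 0]
        assert r.depleted[1, 0] and not r.depleted[0, 0]

    @given(st.lists(peptides_15, min_size=2, max_size=6), st.lists(peptides_15, min_size=2, max_size=6))
    @settings(max_examples=20, deadline=None)
    def test_swapping_sets_inverts_ratios(self, a, b):
        fa, fb = pwm.build_frequency_pwm(a), pwm.build_frequency_pwm(b)
        r_ab = pwm.build_ratio_pwm(fa, fb)
        r_ba = pwm.build_ratio_pwm(fb, fa)
        assert np.allclose(r_ab.ratios * r_ba.ratios, 1.0)

    def test_pseudocount_mismatch_rejected(self):
        a = pwm.build_frequency_pwm(["A" * 15], pseudocount=1)
        b = pwm.build_frequency_pwm(["C" * 15], pseudocount=2)
        with pytest.raises(ConfigurationError):
            pwm.build_ratio_pwm(a, b)


class TestGlobalPropensity:
    def test_identical_lists_give_ones(self):
        peps = ["ACDEFGHIKLMNPQR"]
        gp = pwm.global_propensity(peps, peps)
        assert all(v == pytest.approx(1.0) for v in gp.values())

    def test_direct_ratio_without_smoothing(self):
        binding = ["Y" * 5 + "G" * 5]  # 50% Y
        nonbinding = ["Y" + "G" * 9]  # 10% Y
        gp = pwm.global_propensity(binding, nonbinding, pseudocount=0)
        assert gp["Y"] == pytest.approx(5.0)

    def test_sign_pattern_on_type_I_biased_data(self, assignable_peptides):
        binding = [p.sequence for p in assignable_peptides if p.label == "binding"]
        nonbinding = [p.sequence for p in assignable_peptides if p.label == "non-binding"]
        gp = pwm.global_propensity(binding, nonbinding)
        assert all(gp[aa] > 1 for aa in "YWF")
        assert all(gp[aa] < 1 for aa in "NQE")

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            pwm.global_propensity([], ["A" * 15])


class TestScoring:
    def test_all_ones_matrix_scores_one(self):
        r = pwm.RatioPWM(ratios=np.ones((20, 15)), positional_propensity=np.ones(20))
        score, label = pwm.pwm_score("ACDEFGHIKLMNPQR", pwm.PWMClassifier(r))
        assert score == pytest.approx(1.0)
        assert label == "non-binding"

    def test_hand_product_on_two_position_matrix(self):
        ratios = np.ones((20, 2))
        ratios[0, 0] = 2.0  # A at position 1
        ratios[1, 1] = 3.0  # C at position 2
        r = pwm.RatioPWM(ratios=ratios, positional_propensity=ratios.mean(axis=1))
        score, _ = pwm.pwm_score("AC", pwm.PWMClassifier(r, threshold=2.45))
        assert score == pytest.approx(6.0)

    @pytest.mark.parametrize("score,expected", [(3.0, "binding"), (2.0, "non-binding")])
    def test_default_threshold_2_45(self, score, expected):
        ratios = np.ones((20, 1))
        ratios[0, 0] = score
        r = pwm.RatioPWM(ratios=ratios, positional_propensity=ratios.mean(axis=1))
        _, label = pwm.pwm_score("A", pwm.PWMClassifier(r))
        assert label == expected

    def test_log_additivity_against_direct_product(self, rng):
        ratios = rng.uniform(0.2, 5.0, size=(20, 15))
        r = pwm.RatioPWM(ratios=ratios, positional_propensity=ratios.mean(axis=1))
        pep = "ACDEFGHIKLMNPQR"
        score, _ = pwm.pwm_score(pep, pwm.PWMClassifier(r))
        direct = np.prod([r.ratio(aa, j + 1) for j, aa in enumerate(pep)])
        assert score == pytest.approx(direct)

    def test_sole_binder_scores_maximal_among_variants(self):
        binder = "ACDEFGHIKLMNPQR"
        others = ["CCDEFGHIKLMNPQR", "ACDEFGHIKLMNPQW", "AADEFGHIKLMNPQR"]
        f_b = pwm.build_frequency_pwm([binder], pseudocount=1e-9)
        f_n = pwm.build_frequency_pwm(others, pseudocount=1e-9)
        r = pwm.build_ratio_pwm(f_b, f_n)
        clf = pwm.PWMClassifier(r)
        s_binder, _ = pwm.pwm_score(binder, clf)
        for o in others:
            s_o, _ = pwm.pwm_score(o, clf)
            assert s_binder > s_o

    def test_length_mismatch_rejected(self):
        r = pwm.RatioPWM(ratios=np.ones((20, 15)), positional_propensity=np.ones(20))
        with pytest.raises(InputError):
            pwm.pwm_score("ACD", pwm.PWMClassifier(r))

    def test_auc_above_0_95_on_type_I_only_data(self):
        from conftest import assignable_from_chip

        from earkit import evaluate as ev
        from earkit import peptide_io as pio
        from earkit.synthetic import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(
            n_peptides=3000, seed=2, type2_fraction=0.0, nonbinder_minority_fraction=0.0
        )
        chip, _ = generate_dataset(cfg)
        assignable = assignable_from_chip(chip)
        split = pio.split_train_test(assignable, seed=3)
        b = [p.sequence for p in split.train if p.label == "binding"]
        n = [p.sequence for p in split.train if p.label == "non-binding"]
        ratio = pwm.build_ratio_pwm(pwm.build_frequency_pwm(b), pwm.build_frequency_pwm(n))
        scores = pwm.pwm_scores([p.sequence for p in split.test], pwm.PWMClassifier(ratio))
        assert ev.roc_auc(scores, [p.label for p in split.test]).auc > 0.95


class TestHeatmapExport:
    def test_cluster_off_keeps_native_order(self):
        r = pwm.RatioPWM(ratios=np.ones((20, 15)), positional_propensity=np.ones(20))
        m, rows, cols = pwm.export_heatmap_matrix(r, cluster=False)
        assert rows == list(range(20)) and cols == list(range(15))
        assert m is r.ratios

    def test_identical_rows_become_adjacent(self, rng):
        ratios = rng.uniform(0.5, 2.0, size=(20, 15))
        ratios[7] = ratios[2]  # duplicate row: zero distance, merged first
        r = pwm.RatioPWM(ratios=ratios, positional_propensity=ratios.mean(axis=1))
        _, rows, _ = pwm.export_heatmap_matrix(r, cluster=True)
        pos = {row: i for i, row in enumerate(rows)}
        assert abs(pos[2] - pos[7]) == 1

    def test_three_row_merge_order_matches_pairwise_distances(self):
        # rows 0 and 1 nearly identical, row 2 far away: 0 and 1 merge first
        base = np.ones((20, 15))
        base[0] = 1.0
        base[1] = 1.01
        base[2] = 10.0
        r = pwm.RatioPWM(ratios=base, positional_propensity=base.mean(axis=1))
        _, rows, _ = pwm.export_heatmap_matrix(r, cluster=True)
        pos = {row: i for i, row in enumerate(rows)}
        d01 = np.linalg.norm(base[0] - base[1])
        d02 = np.linalg.norm(base[0] - base[2])
        assert d01 < d02
        assert abs(pos[0] - pos[1]) < abs(pos[0] - pos[2])


def test_threshold_calibration_maximizes_accuracy():
    scores = [0.5, 1.5, 2.5, 3.5]
    labels = ["non-binding", "non-binding", "binding", "binding"]
    t = pwm.calibrate_threshold(scores, labels)
    assert 1.5 < t < 2.5


def test_tsv_roundtrip(tmp_path, rng):
    m = rng.uniform(0.1, 3.0, size=(20, 15))
    path = tmp_path / "pwm.tsv"
    pwm.pwm_to_tsv(m, path)
    back = pwm.pwm_from_tsv(path)
    assert np.allclose(m, back)
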