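"""Sequential stage calling, Fisher discriminant, rank-sum comparisons."""
import numpy as np
import pandas as pd
import pytest

from sizescale import (
    CycleConfig,
    LinearClassifier,
    classify_cell_cycle,
    generate_cell_population,
    make_default_config,
    stage_size_comparison,
    train_linear_classifier,
    train_stage_classifiers,
    verify_s_g2_by_dna,
)
from sizescale.errors import InputError


class TestFisherClassifier:
    def test_direction_matches_closed_form(self):
        # means (0,0) vs (2,0), isotropic unit covariance: Fisher direction (1,0)
        rng = np.random.default_rng(0)
        x0 = rng.standard_normal((400, 2))
        x1 = rng.standard_normal((400, 2)) + [2.0, 0.0]
        clf = train_linear_classifier(np.vstack([x0, x1]), np.r_[np.zeros(400), np.ones(400)])
        w = clf.weights / np.linalg.norm(clf.weights)
        angle = np.degrees(np.arccos(abs(w[0])))
        assert angle < 5.0

    def test_separable_clouds_perfect_accuracy(self):
        x = np.r_[np.zeros((10, 1)), np.ones((10, 1)) * 10]
        y = np.r_[["a"] * 10, ["b"] * 10]
        clf = train_linear_classifier(x, y)
        assert clf.training_accuracy == 1.0

    def test_label_swap_negates_weights(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((60, 3))
        y = np.where(x[:, 0] + 0.3 * rng.standard_normal(60) > 0, "pos", "neg")
        c1 = train_linear_classifier(x, y)
        swapped = np.where(y == "pos", "a_pos", "z_neg")  # reverses sort order
        c2 = train_linear_classifier(x, swapped)
        np.testing.assert_allclose(c2.weights, -c1.weights, rtol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            train_linear_classifier(np.zeros((4, 2)), np.array(["a"] * 4))
        with pytest.raises(InputError):
            train_linear_classifier(np.zeros((3, 2)), np.array(["a", "a", "b"]))


def _toy_cfg():
    spotty = LinearClassifier(
        feature_names=("pcna_spottiness",),
        weights=np.array([1.0]),
        bias=-0.5,
        classes=("G2", "S"),
    )
    return CycleConfig(
        pcna_pos_threshold=0.5, ccna2_pos_threshold=0.5, spotty_classifier=spotty
    )


class TestSequentialClassification:
    def test_hand_traced_walk_of_rules(self):
        # quartile of CCNA2 among the four PCNA+/CCNA2+ cells
        # {0.6, 0.7, 0.8, 0.9} is 0.675, so only 0.6 is early S.
        t = pd.DataFrame(
            {
                "mitotic_flag": [True, False, False, False, False, False, False, False],
                "pcna_mean": [0.9, 0.2, 0.8, 0.8, 0.8, 0.8, 0.8, 0.2],
                "ccna2_mean": [0.9, 0.3, 0.1, 0.6, 0.7, 0.8, 0.9, 0.9],
                "pcna_spottiness": [0.5, 0.1, 0.1, 0.2, 0.1, 0.9, 0.1, 0.1],
            }
        )
        labels = classify_cell_cycle(t, _toy_cfg())
        assert list(labels) == ["M", "G0", "G1", "earlyS", "G2", "S", "G2", "G0"]

    def test_pcna_negative_is_g0_regardless_of_ccna2(self):
        t = pd.DataFrame(
            {
                "pcna_mean": [0.2, 0.8],
                "ccna2_mean": [0.9, 0.1],
                "pcna_spottiness": [0.1, 0.1],
            }
        )
        labels = classify_cell_cycle(t, _toy_cfg())
        assert list(labels) == ["G0", "G1"]

    def test_missing_features_raise(self):
        from sizescale.errors import SchemaError

        with pytest.raises(SchemaError, match="ccna2_mean"):
            classify_cell_cycle(pd.DataFrame({"pcna_mean": [1.0]}), _toy_cfg())

    def test_empty_double_positive_warns(self):
        t = pd.DataFrame(
            {
                "pcna_mean": [0.8, 0.8, 0.2],
                "ccna2_mean": [0.1, 0.2, 0.1],
                "pcna_spottiness": [0.1, 0.2, 0.1],
            }
        )
        with pytest.warns(UserWarning, match="PCNA"):
            labels = classify_cell_cycle(t, _toy_cfg())
        assert list(labels) == ["G1", "G1", "G0"]

    def test_monotone_rescaling_invariance(self):
        t = pd.DataFrame(
            {
                "pcna_mean": [0.2, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8],
                "ccna2_mean": [0.3, 0.1, 0.6, 0.7, 0.8, 0.9, 0.65],
                "pcna_spottiness": [0.1, 0.1, 0.2, 0.1, 0.9, 0.1, 0.8],
            }
        )
        base = classify_cell_cycle(t, _toy_cfg())
        scaled = t.assign(pcna_mean=t["pcna_mean"] * 10)
        cfg2 = CycleConfig(
            pcna_pos_threshold=5.0,
            ccna2_pos_threshold=0.5,
            spotty_classifier=_toy_cfg().spotty_classifier,
        )
        assert list(classify_cell_cycle(scaled, cfg2)) == list(base)

    def test_every_cell_gets_exactly_one_label(self, breast_table):
        labels = classify_cell_cycle(breast_table, train_stage_classifiers(breast_table))
        assert labels.isin(["M", "G0", "G1", "earlyS", "S", "G2"]).all()
        assert len(labels) == len(breast_table)

    def test_label_proportions_track_stage_mix(self, breast_table):
        labels = classify_cell_cycle(breast_table, train_stage_classifiers(breast_table))
        inter = labels[labels != "M"]
        n = len(inter)
        mix = {"G0": 0.10, "G1": 0.40, "earlyS": 0.125, "S": 0.15, "G2": 0.225}
        for stage, p in mix.items():
            se = np.sqrt(p * (1 - p) / n)
            # classification error inflates the spread slightly; 3 SE + 2% slack
            assert abs((inter == stage).mean() - p) < 3 * se + 0.02

    def test_yap_blindness(self, breast_table):
        cfg = train_stage_classifiers(breast_table)
        base = classify_cell_cycle(breast_table, cfg)
        permuted = breast_table.copy()
        rng = np.random.default_rng(0)
        for col in [c for c in permuted.columns if c.startswith("yap_")]:
            permuted[col] = rng.permutation(permuted[col].to_numpy())
        assert list(classify_cell_cycle(permuted, cfg)) == list(base)


class TestDnaVerification:
    def _table(self, dna):
        return pd.DataFrame({"dna_integrated": dna})

    def test_constructed_ordering_passes(self):
        rng = np.random.default_rng(0)
        dna = np.r_[rng.normal(1.0, 0.05, 50), rng.normal(1.5, 0.05, 50), rng.normal(2.0, 0.05, 50)]
        labels = pd.Series(["G1"] * 50 + ["S"] * 50 + ["G2"] * 50)
        rep = verify_s_g2_by_dna(self._table(dna), labels)
        assert rep.passed is True and rep.applicable

    def test_shuffled_labels_usually_fail(self):
        rng = np.random.default_rng(1)
        dna = np.r_[rng.normal(1.0, 0.05, 50), rng.normal(1.5, 0.05, 50), rng.normal(2.0, 0.05, 50)]
        labels = np.array(["G1"] * 50 + ["S"] * 50 + ["G2"] * 50)
        t = self._table(dna)
        passes = 0
        for _ in range(100):
            shuffled = pd.Series(rng.permutation(labels))
            if verify_s_g2_by_dna(t, shuffled).passed:
                passes += 1
        # a random ordering of three near-equal means passes ~1/6 of the time
        assert passes < 40

    def test_missing_stage_not_applicable(self):
        rep = verify_s_g2_by_dna(
            self._table([1.0, 2.0]), pd.Series(["G1", "G2"])
        )
        assert rep.applicable is False and rep.passed is None


class TestStageSizeComparison:
    def _shifted_table(self, seed, n_per=500, shift=1.5):
        rng = np.random.default_rng(seed)
        n = n_per * 8  # 2 stages x 4 bins
        area = np.exp(rng.normal(6, 0.5, n))
        stage = np.r_[["G1"] * (n // 2), ["G2"] * (n // 2)]
        rng.shuffle(stage)
        base = 100 * np.exp(0.2 * rng.standard_normal(n))
        yap = np.where(stage == "G2", shift * base, base)
        return (
            pd.DataFrame({"area": area, "yap_whole_cell_mean": yap}),
            pd.Series(stage),
        )

    def test_exact_small_sample_p(self):
        from sizescale.cell_cycle import _ranksum_p

        # {1,2,3} vs {4,5,6}: 2/20 orderings as extreme -> p = 0.1 exactly
        assert _ranksum_p(np.array([1.0, 2, 3]), np.array([4.0, 5, 6])) == pytest.approx(0.1)
        assert _ranksum_p(np.array([2.0, 2, 2]), np.array([2.0, 2, 2])) == 1.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_planted_shift_detected_in_every_bin(self, seed):
        table, stages = self._shifted_table(seed)
        comp = stage_size_comparison(table, stages, n_size_bins=4)
        within = comp.contrasts[comp.contrasts["kind"] == "stage_within_bin"]
        assert len(within) == 4
        assert (within["p_value"] < 0.05).all()

    def test_small_groups_skipped(self):
        table = pd.DataFrame(
            {"area": np.linspace(1, 2, 8), "yap_whole_cell_mean": np.ones(8)}
        )
        stages = pd.Series(["G1"] * 6 + ["G2"] * 2)
        comp = stage_size_comparison(table, stages, n_size_bins=2)
        within = comp.contrasts[comp.contrasts["kind"] == "stage_within_bin"]
        assert within["skipped"].any()
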