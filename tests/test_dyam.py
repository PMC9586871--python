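"""Masked dynamic-attention fusion model: forward contract, masking,
training behavior."""

import numpy as np
import pytest

from dyam.model import DyAMClassifier, fit_dyam, forward, stack_cohort
from dyam.records import MODALITIES, cohort_labels
from dyam.synthetic import CohortConfig, generate_cohort
from dyam._optim import sigmoid


def hand_model(weights, biases, att_logits):
    """DyAMClassifier with hand-set linear heads on unit-scaled features."""
    model = DyAMClassifier(standardize=False)
    m = len(weights)
    model.modality_names_ = [f"mod{i}" for i in range(m)]
    model.heads_ = []
    for w, b, t in zip(weights, biases, att_logits):
        model.heads_.append({"w": np.asarray(w, float), "b": np.array([b]),
                             "v": np.zeros(len(w)), "c": np.array([t])})
    model.means_ = [np.zeros(len(w)) for w in weights]
    model.scales_ = [np.ones(len(w)) for w in weights]
    model.classes_ = np.array([0, 1])
    model.n_modalities_ = m
    return model


class TestForward:
    def test_weighted_sum_arithmetic_two_modalities(self):
        # equal attention, risks (~1, ~0) => overall ~0.5
        big = 50.0
        model = hand_model([[big], [big]], [0.0, 0.0], [0.0, 0.0])
        X = [np.array([[1.0]]), np.array([[-1.0]])]
        S, A, R, _ = model.forward_components(X)
        np.testing.assert_allclose(A[0], [0.5, 0.5])
        np.testing.assert_allclose(R[0], [1.0, 0.0], atol=1e-12)
        assert S[0] == pytest.approx(0.5, abs=1e-12)

    def test_single_present_modality_bypasses_gate(self):
        model = hand_model([[1.0], [1.0]], [0.2, 0.0], [3.0, -2.0])
        X = [np.array([[0.7]]), np.array([[np.nan]])]
        S, A, R, present = model.forward_components(X)
        assert A[0, 0] == 1.0 and A[0, 1] == 0.0
        assert S[0] == pytest.approx(float(sigmoid(np.array([0.7 * 1.0 + 0.2]))[0]))
        assert not present[0, 1]

    def test_masking_invariance_to_absent_features(self):
        model = hand_model([[1.0, -0.5], [2.0, 0.3]], [0.0, 0.1], [0.5, -0.5])
        present = np.array([[True, False]])
        X1 = [np.array([[0.3, -1.2]]), np.array([[0.0, 0.0]])]
        X2 = [np.array([[0.3, -1.2]]), np.array([[99.0, -99.0]])]
        s1 = model.predict_proba(X1, present=present)
        s2 = model.predict_proba(X2, present=present)
        np.testing.assert_array_equal(s1, s2)

    def test_modality_order_invariance(self):
        model = hand_model([[1.0], [2.0], [-1.0]], [0.1, 0.0, -0.2], [0.3, -0.1, 0.8])
        X = [np.array([[0.4]]), np.array([[np.nan]]), np.array([[-0.6]])]
        s = model.predict_proba(X)[0, 1]
        perm = [2, 0, 1]
        model_p = hand_model([[[1.0], [2.0], [-1.0]][i] for i in perm],
                             [[0.1, 0.0, -0.2][i] for i in perm],
                             [[0.3, -0.1, 0.8][i] for i in perm])
        s_p = model_p.predict_proba([X[i] for i in perm])[0, 1]
        assert s == pytest.approx(s_p, abs=1e-12)

    def test_all_absent_patient_rejected(self):
        model = hand_model([[1.0], [1.0]], [0.0, 0.0], [0.0, 0.0])
        X = [np.array([[np.nan]]), np.array([[np.nan]])]
        with pytest.raises(ValueError, match="every modality absent"):
            model.predict_proba(X)

    def test_gate_off_equals_equal_weight_average(self):
        gated = hand_model([[1.5], [-0.7]], [0.0, 0.2], [1.0, -1.0])
        ungated = hand_model([[1.5], [-0.7]], [0.0, 0.2], [0.0, 0.0])
        ungated.gate = False
        X = [np.array([[0.5], [1.0]]), np.array([[0.1], [np.nan]])]
        _, A, R, present = ungated.forward_components(X)
        np.testing.assert_allclose(A[0], [0.5, 0.5])
        expected = np.where(present, R, 0.0) @ np.array([1.0, 1.0])
        expected[0] /= 2
        np.testing.assert_allclose(ungated.predict_proba(X)[:, 1], expected, atol=1e-12)
        del gated


class TestTraining:
    def test_fixed_seed_identical_parameters(self, small_cohort):
        blocks = stack_cohort(small_cohort)
        y = cohort_labels(small_cohort)
        m1 = DyAMClassifier(random_state=7).fit(blocks, y)
        m2 = DyAMClassifier(random_state=7).fit(blocks, y)
        for h1, h2 in zip(m1.heads_, m2.heads_):
            for k in h1:
                np.testing.assert_array_equal(h1[k], h2[k])

    def test_loss_decreases(self, small_cohort):
        blocks = stack_cohort(small_cohort)
        y = cohort_labels(small_cohort)
        model = DyAMClassifier().fit(blocks, y)
        assert model.loss_curve_[-1] < model.loss_curve_[0]

    def test_degenerate_labels_rejected(self, small_cohort):
        blocks = stack_cohort(small_cohort)
        with pytest.raises(ValueError, match="both classes"):
            DyAMClassifier().fit(blocks, np.zeros(len(small_cohort), dtype=int))

    def test_gated_attention_head_variant_trains(self, small_cohort):
        blocks = stack_cohort(small_cohort)
        y = cohort_labels(small_cohort)
        model = DyAMClassifier(attention_hidden=32).fit(blocks, y)
        assert model.loss_curve_[-1] < model.loss_curve_[0]
        probs = model.predict_proba(blocks)[:, 1]
        assert ((probs >= 0) & (probs <= 1)).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_attention_recovers_genomics_only_signal(self, seed):
        cfg = CohortConfig(n_patients=600,
                           effect_sizes={"ct": 0.0, "ihc": 0.0, "tps": 0.0,
                                         "tmb": 0.5, "genomics": 1.0},
                           seed=seed)
        cohort = generate_cohort(cfg)
        blocks = stack_cohort(cohort)
        y = cohort_labels(cohort)
        model = DyAMClassifier(random_state=seed).fit(blocks, y)
        _, A, _, _ = model.forward_components(blocks)
        # cohort mean of the attention output vector (zeros where absent)
        mean_share = dict(zip(MODALITIES, A.mean(axis=0)))
        assert max(mean_share, key=mean_share.get) == "genomics"


class TestRecordInterface:
    def test_explain_attention_sums_to_one_over_present(self, small_cohort):
        model = fit_dyam(small_cohort)
        blocks = stack_cohort(small_cohort)
        for rec, out in zip(small_cohort, model.explain(blocks)):
            present = rec.presence_mask
            total = sum(out.attention.values())
            assert total == pytest.approx(1.0, abs=1e-9)
            for mod, has in present.items():
                if not has:
                    assert out.attention[mod] == 0.0
                    assert np.isnan(out.partial_risks[mod])

    def test_forward_single_record_matches_batch(self, small_cohort):
        model = fit_dyam(small_cohort)
        blocks = stack_cohort(small_cohort)
        batch = model.explain(blocks)
        out = forward(model, small_cohort[3])
        assert out.overall_score == pytest.approx(batch[3].overall_score, abs=1e-12)
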