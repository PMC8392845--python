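import numpy as np
import pytest

from emgsynergy.errors import DomainError, OrderError, UndefinedStatisticError
from emgsynergy.similarity import max_cc
from emgsynergy.synergy import (
    _normalize_columns,
    compute_vaf,
    estimate_activation,
    nmf_decompose,
    select_synergy_number,
)
from emgsynergy.synthetic_data import SynthSpec, generate_recording


def _planted_matrix(rng, m=4, k=2, n=100, noise=0.0):
    W = rng.random((m, k))
    W /= np.linalg.norm(W, axis=0)
    H = rng.random((k, n))
    A = W @ H
    if noise:
        A = np.clip(A + noise * A.max() * rng.standard_normal(A.shape), 0, None)
    return A, W, H


class TestComputeVaf:
    def test_exact_reconstruction_gives_one(self, rng):
        A, W, H = _planted_matrix(rng)
        assert compute_vaf(A, W, H) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_example(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.array([[1.0], [3.0]])
        H = np.array([[1.0, 0.0]])
        WH_target = np.array([[1.0, 2.0], [3.0, 3.0]])
        # residual Frobenius^2 = 1; centered total = 5  ->  VAF = 0.8
        vaf = 1 - np.sum((A - WH_target) ** 2) / np.sum((A - A.mean()) ** 2)
        assert vaf == pytest.approx(0.8)
        assert compute_vaf(A, np.eye(2), WH_target) == pytest.approx(0.8)

    def test_invariant_to_compensated_rescaling(self, rng):
        A, W, H = _planted_matrix(rng, noise=0.1)
        v1 = compute_vaf(A, W, H)
        v2 = compute_vaf(A, W * 7.5, H / 7.5)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_constant_matrix_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            compute_vaf(np.full((3, 4), 2.0), np.ones((3, 1)), np.ones((1, 4)))


class TestNmfDecompose:
    def test_exact_rank_one(self, rng):
        w = rng.random(4) + 0.1
        h = rng.random(80) + 0.1
        dec = nmf_decompose(np.outer(w, h), 1, rng=0)
        assert dec.vaf >= 0.999

    def test_cost_never_increases(self, rng):
        A, _, _ = _planted_matrix(rng, k=2, noise=0.2)
        dec = nmf_decompose(A, 2, rng=0)
        diffs = np.diff(dec.cost_trace)
        assert np.all(diffs <= 1e-10)

    def test_invariants_of_result(self, rng):
        A, _, _ = _planted_matrix(rng, k=3, noise=0.05)
        dec = nmf_decompose(A, 3, rng=1)
        assert np.all(dec.W >= 0) and np.all(dec.H >= 0)
        np.testing.assert_allclose(np.linalg.norm(dec.W, axis=0), 1.0, atol=1e-9)
        assert compute_vaf(A, dec.W, dec.H) == pytest.approx(dec.vaf, abs=1e-12)

    def test_column_normalization_preserves_product(self, rng):
        W = rng.random((4, 3))
        H = rng.random((3, 50))
        Wn, Hn = _normalize_columns(W, H)
        np.testing.assert_allclose(Wn @ Hn, W @ H, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(Wn, axis=0), 1.0, atol=1e-12)

    def test_seeded_reproducibility(self, rng):
        A, _, _ = _planted_matrix(rng, noise=0.1)
        d1 = nmf_decompose(A, 2, rng=99)
        d2 = nmf_decompose(A, 2, rng=99)
        np.testing.assert_array_equal(d1.W, d2.W)
        np.testing.assert_array_equal(d1.H, d2.H)
        assert d1.init_kind == d2.init_kind

    def test_planted_recovery(self, rng):
        A, W_true, _ = _planted_matrix(rng, k=2, n=100, noise=0.02)
        dec = nmf_decompose(A, 2, rng=0)
        assert max_cc(dec.W, W_true) >= 0.95

    def test_matches_reference_nmf_reconstruction(self, rng):
        """Independent cross-check: the multi-restart factorization should
        reconstruct at least as well as scikit-learn's NMF on the same
        problem (same k, generous iteration budget)."""
        from sklearn.decomposition import NMF

        A, _, _ = _planted_matrix(rng, k=2, noise=0.1)
        dec = nmf_decompose(A, 2, rng=0)
        ref = NMF(n_components=2, init="nndsvda", solver="mu", max_iter=2000, tol=1e-9)
        W_ref = ref.fit_transform(A)
        err_ref = np.linalg.norm(A - W_ref @ ref.components_)
        err_ours = np.linalg.norm(A - dec.W @ dec.H)
        assert err_ours <= err_ref * 1.05 + 1e-9

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            nmf_decompose(np.array([[1.0, -0.1], [0.2, 0.3]]), 1)

    def test_order_above_channels_rejected(self, rng):
        with pytest.raises(OrderError):
            nmf_decompose(rng.random((3, 20)), 4)


class TestEstimateActivation:
    def test_exact_model_recovery(self, rng):
        W = rng.random((4, 1)) + 0.1
        W /= np.linalg.norm(W)
        H_true = rng.random((1, 60)) + 0.1
        H = estimate_activation(W @ H_true, W)
        rel_rms = np.sqrt(np.mean((H - H_true) ** 2)) / np.sqrt(np.mean(H_true**2))
        assert rel_rms < 0.01

    def test_zero_target_drives_h_to_zero(self, rng):
        W = rng.random((4, 2))
        W /= np.linalg.norm(W, axis=0)
        H = estimate_activation(np.zeros((4, 30)), W)
        assert np.all(H < 1e-6)

    def test_output_nonnegative_and_w_untouched(self, rng):
        W = rng.random((4, 2))
        W /= np.linalg.norm(W, axis=0)
        W_copy = W.copy()
        H = estimate_activation(rng.random((4, 40)), W)
        assert np.all(H >= 0)
        np.testing.assert_array_equal(W, W_copy)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(OrderError):
            estimate_activation(rng.random((4, 10)), rng.random((3, 2)))


class TestSelectSynergyNumber:
    def test_exact_rank_one_segments_select_one(self, rng):
        segs = [np.outer(rng.random(4) + 0.1, rng.random(50) + 0.1) for _ in range(3)]
        assert select_synergy_number(segs, rng=0) == 1

    def test_empty_list_rejected(self):
        with pytest.raises(DomainError):
            select_synergy_number([])

    def test_mean_vaf_nondecreasing_in_k(self, rng):
        segs = [_planted_matrix(rng, k=2, noise=0.1)[0] for _ in range(3)]
        means = []
        for k in range(1, 5):
            vafs = [nmf_decompose(s, k, n_random_restarts=5, rng=0).vaf for s in segs]
            means.append(np.mean(vafs))
        assert all(b >= a - 0.01 for a, b in zip(means, means[1:]))


def test_segment_level_recovery_from_synthetic_recording():
    """Full chain on one noiseless-ish recording: preprocess, segment,
    decompose at the planted k, and recover the planted pattern."""
    from emgsynergy.preprocess import (
        attach_envelopes,
        filter_and_rectify,
        normalize_and_envelope,
        segment_motion,
    )

    spec = SynthSpec(n_subjects=1, reps=2, noise_sd=0.02, seed=21)
    rec, truth = generate_recording(spec, "CG01", "CG", "STD")
    rect = np.vstack([filter_and_rectify(ch, rec.fs) for ch in rec.semg])
    env = normalize_and_envelope(rect, rec.fs)
    segs = segment_motion(rec.angle, rec.fs, "STD")
    attach_envelopes(segs, env)
    dec = nmf_decompose(segs[0].envelope_resampled, 2, rng=0)
    assert max_cc(dec.W, truth["W_true"]) >= 0.95
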