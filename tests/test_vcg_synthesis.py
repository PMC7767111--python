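import math

import numpy as np
import pytest

from vcgmi._nn import flatten_params, set_flat_params
from vcgmi.signal_io import MultiLeadRecord
from vcgmi.synthetic_ecg import SimConfig, generate_record, linear_history_mixture
from vcgmi.vcg_synthesis import (
    LSTMLayerParams,
    SynthesizerConfig,
    SynthesizerModel,
    baseline_mlp_synthesizer,
    build_windows,
    cc,
    derive_vcg,
    fidelity_report,
    loss_and_gradients,
    lstm_step,
    rmse,
    train_synthesizer,
)


class TestBuildWindows:
    def test_enumeration_small(self):
        x = np.arange(10.0)
        Y = np.column_stack([x, 2 * x, 3 * x])
        S, T = build_windows(x, Y, 3)
        assert S.shape == (8, 3)
        np.testing.assert_array_equal(S[0], [0, 1, 2])
        np.testing.assert_array_equal(T[0], [2, 4, 6])  # target at sample index 2
        np.testing.assert_array_equal(S[-1], [7, 8, 9])

    def test_window_of_one(self):
        x = np.arange(5.0)
        S, T = build_windows(x, np.tile(x[:, None], 3), 1)
        assert S.shape == (5, 1)
        np.testing.assert_array_equal(S[:, 0], x)
        np.testing.assert_array_equal(T[:, 0], x)

    def test_window_equals_length(self):
        x = np.arange(6.0)
        S, T = build_windows(x, np.zeros((6, 3)), 6)
        assert S.shape == (1, 6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            build_windows(np.arange(3.0), np.zeros((3, 3)), 4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            build_windows(np.arange(5.0), np.zeros((4, 3)), 2)


def _scalar_oracle_step(params, x, h, c):
    """Independent per-unit loop evaluation of the gate equations."""
    H = params.hidden
    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    h_new, c_new = [], []
    for u in range(H):
        af = sum(params.W_f[d, u] * x[d] for d in range(len(x)))
        af += sum(params.U_f[v, u] * h[v] for v in range(H)) + params.b_f[u]
        ai = sum(params.W_i[d, u] * x[d] for d in range(len(x)))
        ai += sum(params.U_i[v, u] * h[v] for v in range(H)) + params.b_i[u]
        ag = sum(params.W_c[d, u] * x[d] for d in range(len(x)))
        ag += sum(params.U_c[v, u] * h[v] for v in range(H)) + params.b_c[u]
        ao = sum(params.W_o[d, u] * x[d] for d in range(len(x)))
        ao += sum(params.U_o[v, u] * h[v] for v in range(H)) + params.b_o[u]
        f, i, g, o = sig(af), sig(ai), math.tanh(ag), sig(ao)
        cn = f * c[u] + i * g
        c_new.append(cn)
        h_new.append(o * math.tanh(cn))
    return np.array(h_new), np.array(c_new)


class TestLstmStep:
    def test_zero_fixed_point(self):
        p = LSTMLayerParams(Wx=np.zeros((2, 12)), Wh=np.zeros((3, 12)), b=np.zeros(12))
        h, c = lstm_step(p, [5.0, -3.0], np.zeros(3), np.zeros(3))
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    def test_gate_saturation_carries_cell_state(self):
        # forget gate ~1, input gate ~0 -> cell state passes through
        b = np.concatenate([[20.0], [-20.0], [0.0], [0.0]])
        p = LSTMLayerParams(Wx=np.zeros((1, 4)), Wh=np.zeros((1, 4)), b=b)
        _, c = lstm_step(p, [0.3], [0.0], [0.7])
        assert abs(float(c) - 0.7) < 1e-6

    def test_single_unit_hand_values(self):
        p = LSTMLayerParams.from_gates(*([[0.5]] * 8), *([[0.0]] * 4))
        h, c = lstm_step(p, [1.0], [0.0], [0.0])
        sig = lambda z: 1.0 / (1.0 + math.exp(-z))
        f = i = o = sig(0.5)
        c_exp = i * math.tanh(0.5)
        h_exp = o * math.tanh(c_exp)
        assert abs(float(c) - c_exp) < 1e-12
        assert abs(float(h) - h_exp) < 1e-12

    @pytest.mark.parametrize("width,in_dim", [(1, 1), (2, 2), (3, 1)])
    def test_matches_scalar_oracle_over_sequence(self, width, in_dim, rng):
        k = 0.7
        p = LSTMLayerParams(
            Wx=rng.uniform(-k, k, size=(in_dim, 4 * width)),
            Wh=rng.uniform(-k, k, size=(width, 4 * width)),
            b=rng.uniform(-k, k, size=4 * width),
        )
        h = np.zeros(width)
        c = np.zeros(width)
        ho = h.copy()
        co = c.copy()
        for _ in range(5):
            x = rng.normal(size=in_dim)
            h, c = lstm_step(p, x, h, c)
            ho, co = _scalar_oracle_step(p, x, ho, co)
            np.testing.assert_allclose(np.atleast_1d(h), ho, atol=1e-10)
            np.testing.assert_allclose(np.atleast_1d(c), co, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        p = LSTMLayerParams(Wx=np.zeros((1, 8)), Wh=np.zeros((2, 8)), b=np.zeros(8))
        with pytest.raises(ValueError, match="shape mismatch"):
            lstm_step(p, [1.0, 2.0], np.zeros(2), np.zeros(2))


def numeric_gradient(model, S, Y, h=1e-5):
    params = model.params
    flat0 = flatten_params(params)
    num = np.zeros_like(flat0)
    for j in range(len(flat0)):
        for sign in (1, -1):
            fp = flat0.copy()
            fp[j] += sign * h
            set_flat_params(params, fp)
            loss, _ = loss_and_gradients(model, S, Y)
            num[j] += sign * loss
    set_flat_params(params, flat0)
    return num / (2 * h)


class TestGradients:
    def test_bptt_matches_numerical(self, rng):
        cfg = SynthesizerConfig(window=4, hidden=2, layers=2, epochs=1, seed=3)
        model = SynthesizerModel.init(cfg, rng)
        S = rng.normal(size=(5, 4))
        Y = rng.normal(size=(5, 3))
        _, grads = loss_and_gradients(model, S, Y)
        analytic = np.concatenate([g.ravel() for g in grads])
        numeric = numeric_gradient(model, S, Y)
        rel = np.abs(numeric - analytic) / np.maximum(1e-6, np.abs(numeric) + np.abs(analytic))
        assert rel.max() < 1e-4


def _constant_target_record(n=1500, value=0.3, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / 500.0
    x = np.sin(2 * np.pi * 1.3 * t) + 0.3 * rng.normal(size=n)
    const = np.full(n, value)
    return MultiLeadRecord("const", 500.0, {"i": x, "vx": const, "vy": const, "vz": const})


SMALL = SynthesizerConfig(
    window=10, hidden=8, layers=2, epochs=20, batch_size=64, train_stride=2, seed=7
)


class TestTrainSynthesizer:
    def test_constant_target_recovery(self):
        rec = _constant_target_record()
        model = train_synthesizer(rec, SMALL)
        derived = derive_vcg(model, rec.lead("i")[-400:])
        for name in ("vx_hat", "vy_hat", "vz_hat"):
            assert rmse(np.full(derived.n_samples, 0.3), derived.lead(name)) < 0.01

    def test_training_loss_decreases(self):
        rec = _constant_target_record()
        model = train_synthesizer(rec, SMALL)
        smooth = np.convolve(model.history, np.ones(3) / 3, mode="valid")
        assert np.all(np.diff(smooth) <= 1e-4)

    def test_seeded_determinism(self):
        rec = _constant_target_record()
        cfg = SynthesizerConfig(window=8, hidden=4, layers=2, epochs=2, seed=11)
        a = train_synthesizer(rec, cfg)
        b = train_synthesizer(rec, cfg)
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa, pb)

    def test_too_short_record_rejected(self):
        rec = _constant_target_record(n=15)
        with pytest.raises(ValueError, match="at least"):
            train_synthesizer(rec, SMALL)


@pytest.fixture(scope="module")
def random_model():
    cfg = SynthesizerConfig(window=12, hidden=6, layers=2, epochs=1, seed=5)
    return SynthesizerModel.init(cfg, np.random.default_rng(5))


class TestDeriveVcg:
    def test_shape_and_names(self, random_model, rng):
        x = rng.normal(size=200)
        out = derive_vcg(random_model, x)
        assert out.lead_names == ["vx_hat", "vy_hat", "vz_hat"]
        assert out.n_samples == 200 - 12 + 1
        assert np.all(np.isfinite(out.as_array()))

    def test_inference_determinism(self, random_model, rng):
        x = rng.normal(size=100)
        a = derive_vcg(random_model, x).as_array()
        b = derive_vcg(random_model, x).as_array()
        np.testing.assert_array_equal(a, b)

    def test_stride_consistency(self, random_model, rng):
        x = rng.normal(size=150)
        k = 7
        full = derive_vcg(random_model, x).as_array()
        shifted = derive_vcg(random_model, x[k:]).as_array()
        np.testing.assert_allclose(shifted, full[k:], atol=1e-12)

    def test_too_short_input_rejected(self, random_model):
        with pytest.raises(ValueError, match="shorter than window"):
            derive_vcg(random_model, np.zeros(5))


class TestBaselineMlpSynthesizer:
    def test_linear_mixing_recovery(self):
        s = generate_record(SimConfig(duration=20.0, mean_rr=0.8, rr_jitter=0.05, seed=13))
        mix = np.zeros((16, 3))
        mix[0, 0] = 1.0
        mix[3, 1] = 0.8
        mix[7, 2] = -0.6
        rec = linear_history_mixture(s.record, mix)
        n = rec.n_samples
        split = int(0.8 * n)
        train = MultiLeadRecord("tr", 500.0, {k: v[:split] for k, v in rec.leads.items()})
        cfg = SynthesizerConfig(window=16, hidden=30, layers=2, epochs=30, batch_size=128, seed=3)
        model = baseline_mlp_synthesizer(train, cfg, hidden=(64, 64))
        test = MultiLeadRecord("te", 500.0, {k: v[split:] for k, v in rec.leads.items()})
        report = fidelity_report(test, derive_vcg(model, test.lead("i")))
        assert all(m["cc"] > 0.9 for m in report.values())

    def test_constant_target(self):
        rec = _constant_target_record()
        model = baseline_mlp_synthesizer(rec, SMALL, hidden=(16, 16))
        derived = derive_vcg(model, rec.lead("i")[-400:])
        for name in ("vx_hat", "vy_hat", "vz_hat"):
            assert rmse(np.full(derived.n_samples, 0.3), derived.lead(name)) < 0.01

    def test_seeded_determinism(self):
        rec = _constant_target_record()
        cfg = SynthesizerConfig(window=8, hidden=4, layers=2, epochs=2, seed=9)
        a = baseline_mlp_synthesizer(rec, cfg, hidden=(8, 8))
        b = baseline_mlp_synthesizer(rec, cfg, hidden=(8, 8))
        for pa, pb in zip(a.net.params, b.net.params):
            np.testing.assert_array_equal(pa, pb)


class TestFidelityMetrics:
    def test_rmse_zero_iff_identical(self, rng):
        v = rng.normal(size=50)
        assert rmse(v, v) == 0.0
        assert rmse(v, v + 1e-6) > 0.0

    def test_rmse_hand_value(self):
        assert rmse([1, 2, 3], [1, 2, 5]) == pytest.approx(np.sqrt(4 / 3))

    def test_rmse_constant_offset(self, rng):
        v = rng.normal(size=64)
        assert rmse(v, v - 0.37) == pytest.approx(0.37)

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            rmse([1, 2], [1, 2, 3])

    def test_cc_positive_scaling_invariance(self, rng):
        v = rng.normal(size=40)
        assert cc(v, 2 * v) == pytest.approx(1.0)
        assert cc(v, 0.001 * v) == pytest.approx(1.0)

    def test_cc_orthogonal(self):
        assert cc([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cc([1, 1], [1, -1]) == pytest.approx(0.0)

    def test_cc_not_shift_invariant(self, rng):
        v = rng.normal(size=40)
        assert cc(v, v + 5.0) != pytest.approx(1.0)

    def test_cc_bounds(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 17))
            assert -1.0 - 1e-12 <= cc(a, b) <= 1.0 + 1e-12

    def test_cc_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cc(np.zeros(5), np.ones(5))
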