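import numpy as np
import pytest

from tbal import _nn
from tbal.model import TBALConfig, TBALModel
from tbal.preprocess import EncodedStay


def _model(F=6, hidden=4, **kw):
    cfg = TBALConfig(input_dim=F, hidden_size=hidden, attention_dim=5,
                     seed=1, **kw)
    return TBALModel.initialize(cfg, [f"f{i}" for i in range(F)],
                                [f"f{i}" for i in range(F)])


def _encoded(T=10, F=6, seed=0):
    rng = np.random.default_rng(seed)
    return EncodedStay(stay_id="s", Z=rng.standard_normal((T, F)),
                       feature_names=[f"f{i}" for i in range(F)],
                       feature_parent=[f"f{i}" for i in range(F)],
                       grid_h=np.arange(float(T)))


class TestForward:
    def test_singleton_prefix_attention_is_one(self):
        model = _model()
        out = model.forward(np.zeros((1, 6)))
        assert out.attention_weights.tolist() == [1.0]
        assert 0.0 < out.risk < 1.0

    def test_attention_simplex(self):
        model = _model()
        enc = _encoded(T=12)
        out = model.forward(enc.Z, trigger_h=11.0, grid_h=enc.grid_h)
        w = out.attention_weights
        assert len(w) == 12 and (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-5)

    def test_deterministic_given_seed(self):
        enc = _encoded()
        r1 = _model().forward(enc.Z).risk
        r2 = _model().forward(enc.Z).risk
        assert r1 == r2

    def test_nan_input_rejected(self):
        model = _model()
        Z = np.zeros((3, 6))
        Z[1, 2] = np.nan
        with pytest.raises(ValueError, match="imputation"):
            model.forward(Z)

    def test_empty_prefix_rejected(self):
        with pytest.raises(ValueError):
            _model().forward(np.zeros((0, 6)))


class TestDynamic:
    def test_equals_prefix_forward(self):
        model = _model()
        enc = _encoded(T=9)
        outs = model.forward_dynamic(enc, [4.0, 8.0])
        ref4 = model.forward(enc.Z[:5], trigger_h=4.0, grid_h=enc.grid_h[:5])
        assert outs[0].risk == ref4.risk
        assert len(outs[0].attention_weights) == 5
        assert len(outs[1].attention_weights) == 9

    def test_causality_future_mutation_has_no_effect(self):
        model = _model()
        enc = _encoded(T=12)
        base = model.forward_dynamic(enc, [5.0])[0].risk
        rng = np.random.default_rng(3)
        for _ in range(20):
            mutated = _encoded(T=12)
            mutated.Z = enc.Z.copy()
            mutated.Z[6:] = rng.standard_normal(mutated.Z[6:].shape) * 10
            assert model.forward_dynamic(mutated, [5.0])[0].risk == base

    def test_off_grid_trigger_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            _model().forward_dynamic(_encoded(), [3.5])


class TestParameterCount:
    def test_hand_counted_minimal_lstm(self):
        cfg = TBALConfig(input_dim=1, hidden_size=1, bidirectional=False,
                         attention=False, time_aware=False)
        model = TBALModel.initialize(cfg)
        counts = model.count_parameters()
        # 4 gates * (input 1 + recurrent 1 + bias 1) = 12, head = w(1)+b(1)
        assert counts["lstm0f"] == 12
        assert counts["head"] == 2
        assert counts["total"] == 14

    def test_bidirectional_doubles_encoder_exactly(self):
        uni = TBALModel.initialize(TBALConfig(
            input_dim=5, hidden_size=7, bidirectional=False,
            attention=False)).count_parameters()
        bi = TBALModel.initialize(TBALConfig(
            input_dim=5, hidden_size=7, bidirectional=True,
            attention=False)).count_parameters()
        assert bi["lstm0f"] + bi["lstm0b"] == 2 * uni["lstm0f"]

    def test_monotone_in_hidden_size(self):
        totals = [TBALModel.initialize(
            TBALConfig(input_dim=5, hidden_size=h)).count_parameters()["total"]
            for h in (4, 8, 16)]
        assert totals[0] < totals[1] < totals[2]


class TestRepresentation:
    def test_feature_permutation_invariance(self):
        model = _model(F=6, bidirectional=True)
        enc = _encoded(T=8)
        base = model.forward(enc.Z).risk
        perm = np.random.default_rng(0).permutation(6)
        permuted = _model(F=6, bidirectional=True)
        for key in ("lstm0f.Wx", "lstm0b.Wx"):
            permuted.params[key] = model.params[key][perm]
        out = permuted.forward(enc.Z[:, perm]).risk
        assert out == pytest.approx(base, abs=1e-12)

    def test_time_aware_attention_sees_grid_spacing(self):
        model = _model()
        Z = np.random.default_rng(1).standard_normal((6, 6))
        dense = model.forward(Z, trigger_h=5.0,
                              grid_h=np.arange(6.0)).attention_weights
        sparse = model.forward(Z, trigger_h=50.0,
                               grid_h=np.array([0.0, 10, 20, 30, 40, 50.0])
                               ).attention_weights
        assert not np.allclose(dense, sparse)

    def test_uniform_time_shift_invariance_without_time_awareness(self):
        model = _model(time_aware=False)
        Z = np.random.default_rng(2).standard_normal((6, 6))
        a = model.forward(Z, trigger_h=5.0, grid_h=np.arange(6.0)).risk
        b = model.forward(Z, trigger_h=105.0,
                          grid_h=np.arange(6.0) + 100.0).risk
        assert a == pytest.approx(b, abs=1e-12)


class TestBackwardPass:
    @pytest.mark.parametrize("kw", [
        dict(bidirectional=True, attention=True, time_aware=True),
        dict(bidirectional=False, attention=False, time_aware=False),
        dict(bidirectional=True, attention=True, num_layers=2),
    ])
    def test_gradients_match_finite_differences(self, kw):
        cfg = TBALConfig(input_dim=3, hidden_size=3, attention_dim=4,
                         seed=2, **kw)
        params = _nn.init_params(cfg, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((2, 4, 3))
        lengths = np.array([4, 2])
        tau = rng.uniform(0, 30, (2, 4))
        y = np.array([1.0, 0.0])

        def loss(params, Z):
            prob, _, cache = _nn.forward(params, cfg, Z, lengths, tau=tau)
            p = np.clip(prob, 1e-12, 1 - 1e-12)
            return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)), \
                prob, cache

        L, prob, cache = loss(params, Z)
        grads = _nn.backward(params, cfg, cache, (prob - y) / len(y))
        eps = 1e-6
        rng2 = np.random.default_rng(5)
        for key in list(params) + ["_input"]:
            target = Z if key == "_input" else params[key]
            flat = target.reshape(-1)
            for _ in range(4):       # spot-check a few coordinates per tensor
                i = int(rng2.integers(flat.size))
                old = flat[i]
                flat[i] = old + eps
                Lp = loss(params, Z)[0]
                flat[i] = old - eps
                Lm = loss(params, Z)[0]
                flat[i] = old
                num = (Lp - Lm) / (2 * eps)
                ana = grads[key].reshape(-1)[i]
                assert ana == pytest.approx(num, abs=1e-6)


class TestCheckpoint:
    def test_save_load_preserves_outputs(self, tmp_path):
        model = _model()
        enc = _encoded()
        model.save(tmp_path / "ckpt.npz")
        back = TBALModel.load(tmp_path / "ckpt.npz")
        assert back.forward(enc.Z).risk == model.forward(enc.Z).risk
        assert back.feature_names == model.feature_names
        assert back.config == model.config
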