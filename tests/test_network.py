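"""Forward-pass contracts: attention pooling, fusion, control token, routing."""

import copy

import numpy as np
import pytest

from pansurv import autograd as ag
from pansurv.autograd import Tensor
from pansurv.core import ValidationError
from pansurv.network import (
    ModelConfig,
    amil_aggregate,
    cancer_control_token,
    forward_tensor,
    fuse_modalities,
    init_params,
    load_checkpoint,
    model_forward,
    route_experts,
    save_checkpoint,
)

from conftest import make_record


class TestModelConfig:
    def test_divisibility_enforced(self):
        with pytest.raises(ValidationError):
            ModelConfig(D=8, K=2, d=10, n_tokens=3)

    def test_defaults_derive_from_k(self):
        cfg = ModelConfig(D=8, K=5, d=8, n_tokens=2, n_heads=2)
        assert cfg.n_experts == 5
        assert cfg.boost == pytest.approx(np.log(5))

    def test_top_k_bounds(self):
        with pytest.raises(ValidationError):
            ModelConfig(D=8, K=2, d=8, n_tokens=2, n_heads=2, top_k=5, n_experts=2)


class TestAmil:
    def test_singleton_bag_attention_one(self, tiny_params):
        out = amil_aggregate(np.random.default_rng(0).standard_normal((1, 8)), tiny_params)
        assert out.attn == pytest.approx([1.0])

    def test_identical_rows_uniform_attention(self, tiny_params):
        row = np.random.default_rng(1).standard_normal(8)
        out = amil_aggregate(np.tile(row, (6, 1)), tiny_params)
        assert out.attn == pytest.approx(np.full(6, 1 / 6), abs=1e-6)

    def test_attention_normalized_and_permutation_equivariant(self, tiny_params):
        rng = np.random.default_rng(2)
        bag = rng.standard_normal((9, 8))
        out = amil_aggregate(bag, tiny_params)
        assert out.attn.sum() == pytest.approx(1.0, abs=1e-6)
        perm = rng.permutation(9)
        out_p = amil_aggregate(bag[perm], tiny_params)
        assert out_p.attn == pytest.approx(out.attn[perm], abs=1e-9)
        assert out_p.H1 == pytest.approx(out.H1, abs=1e-9)

    def test_empty_bag_rejected(self, tiny_params):
        with pytest.raises(ValidationError):
            amil_aggregate(np.zeros((0, 8)), tiny_params)


class TestFusion:
    def test_single_token_attention_is_value_projection(self):
        cfg = ModelConfig(D=8, K=2, d_slide=8, d=8, n_tokens=1, n_heads=1,
                          attn_hidden=8, expert_hidden=8)
        params = init_params(cfg, seed=3)
        H1 = np.random.default_rng(0).standard_normal(8)
        out = fuse_modalities(H1, np.zeros(8), params, cfg)
        # softmax over one key is exactly 1 -> A_c2h = E_h @ Wv
        expected = out.E_h @ params["xattn.c2h.Wv"].data
        assert out.A_c_to_h.ravel() == pytest.approx(expected.ravel(), abs=1e-12)

    def test_zero_clinical_vector_finite(self, tiny_params, tiny_config):
        out = fuse_modalities(np.ones(8), np.zeros(8), tiny_params, tiny_config)
        for field in (out.E_h, out.E_c, out.A_c_to_h, out.A_h_to_c, out.fused):
            assert np.all(np.isfinite(field))

    def test_hand_computed_two_token_attention(self):
        """d=4, 2 tokens of size 2, one head, hand-set weights."""
        cfg = ModelConfig(D=4, K=2, d_slide=4, d=4, n_tokens=2, n_heads=1,
                          attn_hidden=4, expert_hidden=4)
        params = init_params(cfg, seed=0)
        I2 = np.eye(2)
        for name in ("Wq", "Wk", "Wv"):
            params[f"xattn.c2h.{name}"] = Tensor(I2, requires_grad=True)
        Th = np.array([[1.0, 0.0], [0.0, 2.0]])   # histology tokens (keys/values)
        Tc = np.array([[1.0, 1.0], [2.0, 0.0]])   # clinical tokens (queries)
        from pansurv.network import _multihead_cross_attention

        out = _multihead_cross_attention(Tensor(Tc), Tensor(Th), params, "xattn.c2h", 1)
        # hand computation: scores = Tc @ Th.T / sqrt(2), rows softmaxed
        scores = Tc @ Th.T / np.sqrt(2)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        assert out.data == pytest.approx(w @ Th, abs=1e-12)


class TestControlToken:
    def test_deterministic_per_index(self, tiny_params, tiny_config):
        t1 = cancer_control_token([1, 0], tiny_params)
        t2 = cancer_control_token([1, 0], tiny_params)
        assert np.array_equal(t1, t2)

    def test_instance_norm_contract(self, tiny_params):
        for onehot in ([1, 0], [0, 1]):
            t = cancer_control_token(onehot, tiny_params)
            assert t.mean() == pytest.approx(0.0, abs=1e-5)
            assert t.var() == pytest.approx(1.0, abs=1e-5)

    def test_non_onehot_rejected(self, tiny_params):
        with pytest.raises(ValidationError):
            cancer_control_token([0.5, 0.5], tiny_params)

    def test_hand_computed_silu_chain(self):
        """K=2, d=2: scalar-by-scalar SiLU then normalization."""
        cfg = ModelConfig(D=4, K=2, d_slide=4, d=2, n_tokens=1, n_heads=1,
                          attn_hidden=4, expert_hidden=4)
        params = init_params(cfg, seed=0)
        params["token.W1"] = Tensor(np.array([[1.0, -2.0], [0.0, 0.0]]), requires_grad=True)
        params["token.b1"] = Tensor(np.zeros(2), requires_grad=True)
        params["token.W2"] = Tensor(np.array([[3.0, 1.0], [0.5, -1.0]]), requires_grad=True)
        params["token.b2"] = Tensor(np.zeros(2), requires_grad=True)
        t = cancer_control_token([1, 0], params)
        sig = lambda x: 1 / (1 + np.exp(-x))
        h = np.array([1.0 * sig(1.0), -2.0 * sig(-2.0)])
        raw = h @ np.array([[3.0, 1.0], [0.5, -1.0]])
        expected = (raw - raw.mean()) / np.sqrt(raw.var() + 1e-10)
        assert t.ravel() == pytest.approx(expected, abs=1e-9)


class TestRouter:
    def test_saturating_boost_selects_own_expert(self, tiny_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, boost=50.0)
        params = init_params(cfg, seed=1)
        fused = np.random.default_rng(0).standard_normal(cfg.d)
        token = cancer_control_token([0, 1], params)
        out = route_experts(fused, token, 1, params, cfg)
        assert out.gates[1] == pytest.approx(1.0, abs=1e-6)
        assert out.risk == pytest.approx(out.expert_risks[1], abs=1e-6)

    def test_uniform_gates_under_symmetry(self, tiny_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, boost=0.0, top_k=2, n_experts=2)
        params = init_params(cfg, seed=2)
        params["router.gate.W"] = Tensor(np.zeros_like(params["router.gate.W"].data),
                                         requires_grad=True)
        params["router.gate.b"] = Tensor(np.zeros(2), requires_grad=True)
        fused = np.ones(cfg.d)
        token = cancer_control_token([1, 0], params)
        out = route_experts(fused, token, 0, params, cfg)
        assert out.gates == pytest.approx([0.5, 0.5])

    def test_hand_computed_topk_renormalization(self):
        """3 experts, top 2, hand-set logits and boost ln 2 on index 1."""
        cfg = ModelConfig(D=4, K=3, d_slide=4, d=4, n_tokens=1, n_heads=1,
                          attn_hidden=4, expert_hidden=4, n_experts=3, top_k=2,
                          boost=float(np.log(2)))
        params = init_params(cfg, seed=0)
        params["router.gate.W"] = Tensor(np.zeros((4, 3)), requires_grad=True)
        params["router.gate.b"] = Tensor(np.array([1.0, 0.5, 0.1]), requires_grad=True)
        fused = np.zeros(4)
        token = cancer_control_token([0, 1, 0], params)
        out = route_experts(fused, token, 1, params, cfg)
        logits = np.array([1.0, 0.5 + np.log(2), 0.1])
        full = np.exp(logits) / np.exp(logits).sum()
        full[2] = 0.0                       # smallest dropped
        expected_gates = full / full.sum()
        assert out.gates == pytest.approx(expected_gates, abs=1e-12)
        assert out.risk == pytest.approx(float(out.expert_risks @ expected_gates), abs=1e-9)

    def test_gate_support_exactly_top_k(self, tiny_config):
        params = init_params(tiny_config, seed=3)
        fused = np.random.default_rng(1).standard_normal(tiny_config.d)
        token = cancer_control_token([1, 0], params)
        out = route_experts(fused, token, 0, params, tiny_config)
        assert (out.gates > 0).sum() == min(tiny_config.top_k, tiny_config.n_experts)
        assert out.gates.sum() == pytest.approx(1.0, abs=1e-9)

    def test_boost_monotone_in_own_gate(self, tiny_config):
        import dataclasses

        rng = np.random.default_rng(4)
        fused = rng.standard_normal(tiny_config.d)
        gates = []
        for boost in (0.0, 0.5, 1.0, 2.0, 5.0):
            cfg = dataclasses.replace(tiny_config, boost=boost)
            params = init_params(cfg, seed=5)
            token = cancer_control_token([1, 0], params)
            gates.append(route_experts(fused, token, 0, params, cfg).gates[0])
        assert all(a <= b + 1e-12 for a, b in zip(gates, gates[1:]))


class TestModelForward:
    def test_deterministic(self, tiny_params, tiny_config):
        rec = make_record(n=6, d=8)
        r1 = model_forward(rec, tiny_params, tiny_config)
        r2 = model_forward(rec, tiny_params, tiny_config)
        assert r1.risk == r2.risk

    def test_patch_permutation_invariance(self, tiny_params, tiny_config):
        rec = make_record(n=7, d=8)
        rec2 = copy.deepcopy(rec)
        perm = np.random.default_rng(0).permutation(7)
        rec2.bags[0].features = rec2.bags[0].features[perm]
        rec2.bags[0].coords = rec2.bags[0].coords[perm]
        r1 = model_forward(rec, tiny_params, tiny_config)
        r2 = model_forward(rec2, tiny_params, tiny_config)
        assert r1.risk == pytest.approx(r2.risk, abs=1e-6)

    def test_duplicating_symmetric_bag_rows_keeps_risk(self, tiny_params, tiny_config):
        rec = make_record(n=1, d=8)
        row = rec.bags[0].features[0]
        rec_dup = copy.deepcopy(rec)
        rec_dup.bags[0].features = np.tile(row, (4, 1))
        rec_dup.bags[0].coords = np.array([[0, 0], [224, 0], [0, 224], [224, 224]],
                                          dtype=np.int32)
        r1 = model_forward(rec, tiny_params, tiny_config)
        r2 = model_forward(rec_dup, tiny_params, tiny_config)
        assert r1.risk == pytest.approx(r2.risk, abs=1e-5)

    @pytest.mark.parametrize("seed", range(3))
    def test_no_nan_on_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        cfg = ModelConfig(
            D=int(rng.integers(4, 12)), K=int(rng.integers(2, 5)),
            d_slide=16, d=16, n_tokens=int(rng.choice([1, 2, 4])),
            n_heads=int(rng.choice([1, 2])), attn_hidden=8, expert_hidden=8,
        )
        params = init_params(cfg, seed=seed)
        rec = make_record(n=5, d=cfg.D, K=cfg.K, cancer_index=cfg.K - 1)
        pred = model_forward(rec, params, cfg)
        assert np.isfinite(pred.risk)
        assert np.all(np.isfinite(pred.attn)) and np.all(np.isfinite(pred.gates))

    def test_gradcheck_tiny_model(self, tiny_config):
        """Analytic risk gradients vs central differences on every parameter."""
        params = init_params(tiny_config, seed=6)
        rec = make_record(n=4, d=8)
        risk, _ = forward_tensor(rec, params, tiny_config)
        ag.backward(risk)
        rng = np.random.default_rng(0)
        checked = 0
        for name, p in params.items():
            if p.grad is None:     # unselected experts legitimately get no grad
                continue
            flat = p.data.ravel()
            for idx in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                rp, _ = forward_tensor(rec, params, tiny_config)
                flat[idx] = orig - eps
                rm, _ = forward_tensor(rec, params, tiny_config)
                flat[idx] = orig
                num = (rp.item() - rm.item()) / (2 * eps)
                if abs(num) > 1e-10:
                    assert p.grad.ravel()[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)
                    checked += 1
        assert checked > 20


class TestCheckpoint:
    def test_round_trip(self, tiny_params, tiny_config, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, tiny_params, tiny_config, cancer_labels=("A", "B"))
        params, cfg, labels = load_checkpoint(path)
        assert labels == ("A", "B")
        assert cfg == tiny_config
        for k, v in tiny_params.items():
            assert np.array_equal(params[k].data, v.data)

    def test_predictions_survive_round_trip(self, tiny_params, tiny_config, tmp_path):
        rec = make_record(n=5, d=8)
        before = model_forward(rec, tiny_params, tiny_config).risk
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, tiny_params, tiny_config)
        params, cfg, _ = load_checkpoint(path)
        assert model_forward(rec, params, cfg).risk == pytest.approx(before, abs=1e-12)
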