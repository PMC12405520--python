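"""Forward pass of the router-fused attention-MIL survival network.

The architecture, end to end for one patient:

1. **Attention MIL** — the pooled N x D patch matrix is embedded to a slide
   space (``d_slide``), pooled with gated attention (tanh branch ⊙ sigmoid
   branch) into a single slide summary H1 (1 x d_slide).
2. **Cross-attention fusion** — H1 and the clinical vector C (1 x M) are
   projected by two symmetric MLPs into a shared latent space (1 x d), each
   embedding is reshaped into ``n_tokens`` sub-tokens, and multi-head
   cross-attention is computed in both directions (clinical queries over
   histology tokens and vice versa); the two attended summaries are linearly
   fused back to 1 x d.
3. **Cancer control token** — the cancer-type one-hot is mapped through a
   two-layer SiLU network and instance-normalized into a 1 x d token.
4. **Cancer-aware expert router** — gate logits are a linear projection of the
   token, the patient's own-cancer logit receives an additive logarithmic
   boost, the softmax gates are restricted to the top-k experts and
   renormalized, and the risk is the gated sum of per-expert MLP outputs on
   the channelwise concatenation [fused ‖ token].

The scalar output is a log-risk: higher means shorter expected survival.
All functions build an autodiff graph when handed parameter Tensors, so the
same code path serves training and inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .core import (
    CancerTypeCode,
    PatientRecord,
    ValidationError,
    DimensionError,
    pool_patient_bag,
)


@dataclass
class ModelConfig:
    D: int                       # patch feature dim
    K: int                       # number of cancer types
    M: int = 8                   # clinical vector length
    d_slide: int = 768           # slide summary dim
    d: int = 256                 # fusion latent dim
    n_tokens: int = 4            # sub-tokens per modality
    n_heads: int = 4             # attention heads
    attn_hidden: int = 256       # gated-attention hidden width
    n_experts: int | None = None  # default: one expert per cancer type
    top_k: int = 2
    boost: float | None = None   # default: ln(K)
    expert_hidden: int = 128
    gate_on_fused: bool = False  # alternative: gate logits see [fused ‖ token]
    residual: bool = False       # query-side residual inside each attention block
    seed: int = 0

    def __post_init__(self):
        if self.n_experts is None:
            self.n_experts = self.K
        if self.boost is None:
            self.boost = float(np.log(max(self.K, 2)))
        if self.d % self.n_tokens != 0:
            raise ValidationError("d must be divisible by n_tokens")
        if (self.d // self.n_tokens) % self.n_heads != 0:
            raise ValidationError("token dim d/n_tokens must be divisible by n_heads")
        if not 1 <= self.top_k <= self.n_experts:
            raise ValidationError("need 1 <= top_k <= n_experts")
        if self.boost < 0:
            raise ValidationError("boost must be >= 0")


@dataclass
class AttentionOutput:
    H1: np.ndarray       # (d_slide,)
    attn: np.ndarray     # (N,) softmax weights


@dataclass
class FusionOutput:
    E_h: np.ndarray
    E_c: np.ndarray
    A_c_to_h: np.ndarray
    A_h_to_c: np.ndarray
    fused: np.ndarray


@dataclass
class RouterOutput:
    token: np.ndarray
    gates: np.ndarray
    expert_risks: np.ndarray
    risk: float


@dataclass
class RiskPrediction:
    patient_id: str
    risk: float
    attn: np.ndarray
    attn_provenance: list[tuple[str, int]]
    gates: np.ndarray


# ------------------------------------------------------------ initialization
def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def init_params(config: ModelConfig, seed: int | None = None) -> dict[str, Tensor]:
    """Seeded Glorot-uniform initialization of every trainable weight."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    d, ds, dt = config.d, config.d_slide, config.d // config.n_tokens
    p: dict[str, np.ndarray] = {}

    # AMIL: patch embedding + gated attention
    p["amil.embed.W"] = _glorot(rng, config.D, ds)
    p["amil.embed.b"] = np.zeros(ds)
    p["amil.V"] = _glorot(rng, ds, config.attn_hidden)
    p["amil.U"] = _glorot(rng, ds, config.attn_hidden)
    p["amil.w"] = _glorot(rng, config.attn_hidden, 1)
    # per-cancer linear instance-risk probe (anchors attention polarity)
    p["amil.probe"] = _glorot(rng, ds, config.K)

    # fusion projection MLPs (symmetric: d_slide->d and M->d, one hidden layer)
    p["fuse.h.W1"] = _glorot(rng, ds, d)
    p["fuse.h.b1"] = np.zeros(d)
    p["fuse.h.W2"] = _glorot(rng, d, d)
    p["fuse.h.b2"] = np.zeros(d)
    p["fuse.c.W1"] = _glorot(rng, config.M, d)
    p["fuse.c.b1"] = np.zeros(d)
    p["fuse.c.W2"] = _glorot(rng, d, d)
    p["fuse.c.b2"] = np.zeros(d)

    # cross-attention projections, one set per direction
    for direction in ("c2h", "h2c"):
        for name in ("Wq", "Wk", "Wv"):
            p[f"xattn.{direction}.{name}"] = _glorot(rng, dt, dt)
    p["fuse.out.W"] = _glorot(rng, 2 * d, d)
    p["fuse.out.b"] = np.zeros(d)

    # cancer control token network (two layers, SiLU, then instance norm)
    p["token.W1"] = _glorot(rng, config.K, d)
    p["token.b1"] = np.zeros(d)
    p["token.W2"] = _glorot(rng, d, d)
    p["token.b2"] = np.zeros(d)

    # router: gate projection + expert pool.  Zero-initialized (standard MoE
    # practice) so the own-cancer boost alone decides the initial routing and
    # expert specialization can lock in.
    gate_in = 3 * d if config.gate_on_fused else d
    p["router.gate.W"] = np.zeros((gate_in, config.n_experts))
    p["router.gate.b"] = np.zeros(config.n_experts)
    for e in range(config.n_experts):
        p[f"expert.{e}.W1"] = _glorot(rng, 2 * d, config.expert_hidden)
        p[f"expert.{e}.b1"] = np.zeros(config.expert_hidden)
        p[f"expert.{e}.W2"] = _glorot(rng, config.expert_hidden, 1)
        p[f"expert.{e}.b2"] = np.zeros(1)

    return {k: Tensor(v, requires_grad=True) for k, v in p.items()}


# --------------------------------------------------------------- sub-forwards
def _check_finite(x: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"non-finite values in {what}")


def amil_forward(
    bag: np.ndarray, params: dict[str, Tensor], return_internals: bool = False
):
    """Gated-attention pooling; returns (H1 [1 x d_slide], attn [N]) tensors.

    With ``return_internals`` also returns the raw attention scores and the
    embedded patches (used by the trainer's attention-anchoring term).
    """
    bag = np.asarray(bag, dtype=np.float64)
    if bag.ndim != 2 or bag.shape[0] < 1:
        raise ValidationError("bag must be a nonempty N x D matrix")
    _check_finite(bag, "feature bag")
    X = Tensor(bag)
    E = ag.add(ag.matmul(X, params["amil.embed.W"]), params["amil.embed.b"])  # N x ds
    gate = ag.mul(
        ag.tanh(ag.matmul(E, params["amil.V"])),
        ag.sigmoid(ag.matmul(E, params["amil.U"])),
    )                                                                          # N x h
    scores = ag.reshape(ag.matmul(gate, params["amil.w"]), (-1,))              # N
    attn = ag.softmax(scores, axis=0)
    H1 = ag.matmul(ag.reshape(attn, (1, -1)), E)                               # 1 x ds
    if return_internals:
        return H1, attn, scores, E
    return H1, attn


def amil_aggregate(bag: np.ndarray, params: dict[str, Tensor]) -> AttentionOutput:
    H1, attn = amil_forward(bag, params)
    return AttentionOutput(H1=H1.data.ravel().copy(), attn=attn.data.copy())


def _mlp2(x: Tensor, params: dict[str, Tensor], prefix: str) -> Tensor:
    h = ag.silu(ag.add(ag.matmul(x, params[f"{prefix}.W1"]), params[f"{prefix}.b1"]))
    return ag.add(ag.matmul(h, params[f"{prefix}.W2"]), params[f"{prefix}.b2"])


def _multihead_cross_attention(
    queries: Tensor, keys: Tensor, params: dict[str, Tensor], prefix: str,
    n_heads: int, residual: bool = False,
) -> Tensor:
    """Scaled dot-product attention, queries (T x dt) over keys/values (S x dt)."""
    Q = ag.matmul(queries, params[f"{prefix}.Wq"])
    K = ag.matmul(keys, params[f"{prefix}.Wk"])
    V = ag.matmul(keys, params[f"{prefix}.Wv"])
    T, dt = Q.shape
    S = K.shape[0]
    dk = dt // n_heads
    # (T, dt) -> (n_heads, T, dk); all heads attend in one batched matmul
    Qh = ag.transpose(ag.reshape(Q, (T, n_heads, dk)), (1, 0, 2))
    Kh = ag.transpose(ag.reshape(K, (S, n_heads, dk)), (1, 0, 2))
    Vh = ag.transpose(ag.reshape(V, (S, n_heads, dk)), (1, 0, 2))
    scores = ag.mul(ag.bmm(Qh, ag.transpose(Kh, (0, 2, 1))), 1.0 / np.sqrt(dk))
    w = ag.softmax(scores, axis=-1)
    out = ag.bmm(w, Vh)                                     # (n_heads, T, dk)
    out = ag.reshape(ag.transpose(out, (1, 0, 2)), (T, dt))
    if residual:
        out = ag.add(out, queries)          # standard transformer residual
    return out


def fuse_forward(
    H1: Tensor, C: np.ndarray, params: dict[str, Tensor], config: ModelConfig
) -> tuple[Tensor, dict[str, Tensor]]:
    """Cross-attention fusion; returns (fused [1 x d], intermediates)."""
    C = np.asarray(C, dtype=np.float64).reshape(1, -1)
    if C.shape[1] != config.M:
        raise DimensionError(f"clinical vector length {C.shape[1]} != M={config.M}")
    _check_finite(C, "clinical vector")
    E_h = _mlp2(H1, params, "fuse.h")                     # 1 x d
    E_c = _mlp2(Tensor(C), params, "fuse.c")              # 1 x d
    dt = config.d // config.n_tokens
    Th = ag.reshape(E_h, (config.n_tokens, dt))           # histology sub-tokens
    Tc = ag.reshape(E_c, (config.n_tokens, dt))           # clinical sub-tokens
    A_c2h = _multihead_cross_attention(Tc, Th, params, "xattn.c2h", config.n_heads,
                                       residual=config.residual)
    A_h2c = _multihead_cross_attention(Th, Tc, params, "xattn.h2c", config.n_heads,
                                       residual=config.residual)
    A_c2h_flat = ag.reshape(A_c2h, (1, config.d))
    A_h2c_flat = ag.reshape(A_h2c, (1, config.d))
    fused = ag.add(
        ag.matmul(ag.concat([A_c2h_flat, A_h2c_flat], axis=1), params["fuse.out.W"]),
        params["fuse.out.b"],
    )
    aux = {"E_h": E_h, "E_c": E_c, "A_c_to_h": A_c2h_flat, "A_h_to_c": A_h2c_flat}
    return fused, aux


def fuse_modalities(
    H1: np.ndarray, C: np.ndarray, params: dict[str, Tensor], config: ModelConfig
) -> FusionOutput:
    fused, aux = fuse_forward(Tensor(np.asarray(H1, dtype=float).reshape(1, -1)), C, params, config)
    return FusionOutput(
        E_h=aux["E_h"].data.copy(),
        E_c=aux["E_c"].data.copy(),
        A_c_to_h=aux["A_c_to_h"].data.copy(),
        A_h_to_c=aux["A_h_to_c"].data.copy(),
        fused=fused.data.copy(),
    )


def token_forward(onehot: np.ndarray, params: dict[str, Tensor]) -> Tensor:
    """Cancer control token: InstanceNorm(W2 · SiLU(W1 · onehot))."""
    onehot = np.asarray(onehot, dtype=np.float64).reshape(1, -1)
    if not (np.isclose(onehot.sum(), 1.0) and np.all((onehot == 0) | (onehot == 1))):
        raise ValidationError("cancer code must be one-hot")
    h = ag.silu(ag.add(ag.matmul(Tensor(onehot), params["token.W1"]), params["token.b1"]))
    t = ag.add(ag.matmul(h, params["token.W2"]), params["token.b2"])      # 1 x d
    mean = ag.tensor_mean(t, axis=1, keepdims=True)
    centered = ag.add(t, ag.mul(mean, -1.0))
    var = ag.tensor_mean(ag.mul(centered, centered), axis=1, keepdims=True)
    return ag.mul(centered, ag.power(ag.add(var, 1e-10), -0.5))


def cancer_control_token(onehot: np.ndarray, params: dict[str, Tensor]) -> np.ndarray:
    return token_forward(onehot, params).data.copy()


def route_forward(
    fused: Tensor,
    token: Tensor,
    cancer_index: int,
    params: dict[str, Tensor],
    config: ModelConfig,
    compute_all: bool = False,
) -> tuple[Tensor, Tensor, Tensor]:
    """Expert routing; returns (risk scalar, gates [n_experts], expert_risks).

    Unselected experts get exactly zero gate, so their forwards are skipped
    during training; ``compute_all`` forces them (for inspection) — the risk
    is unchanged either way.
    """
    if not 0 <= cancer_index < config.K:
        raise ValidationError(f"cancer_index {cancer_index} outside [0, {config.K})")
    x = ag.concat([fused, token], axis=1)                 # 1 x 2d  dynamic feature
    gate_in = ag.concat([x, token], axis=1) if config.gate_on_fused else token
    logits = ag.add(ag.matmul(gate_in, params["router.gate.W"]), params["router.gate.b"])
    boost_vec = np.zeros(config.n_experts)
    boost_vec[cancer_index] = config.boost
    logits = ag.add(logits, Tensor(boost_vec.reshape(1, -1)))
    logits = ag.reshape(logits, (-1,))

    full = ag.softmax(logits, axis=0)
    # top-k selection: zero non-selected gates, renormalize the surviving mass
    order = np.argsort(-full.data, kind="stable")
    selected = order[: config.top_k]
    mask = np.zeros(config.n_experts)
    mask[selected] = 1.0
    masked = ag.mul(full, Tensor(mask))
    gates = ag.mul(masked, ag.power(ag.tensor_sum(masked), -1.0))

    risks = []
    for e in range(config.n_experts):
        if mask[e] or compute_all:
            risks.append(ag.reshape(_mlp2(x, params, f"expert.{e}"), (1,)))
        else:
            risks.append(Tensor(np.zeros(1)))
    expert_risks = ag.concat(risks, axis=0)
    risk = ag.tensor_sum(ag.mul(gates, expert_risks))
    return risk, gates, expert_risks


def route_experts(
    fused: np.ndarray,
    token: np.ndarray,
    cancer_index: int,
    params: dict[str, Tensor],
    config: ModelConfig,
) -> RouterOutput:
    risk, gates, expert_risks = route_forward(
        Tensor(np.asarray(fused, dtype=float).reshape(1, -1)),
        Tensor(np.asarray(token, dtype=float).reshape(1, -1)),
        cancer_index,
        params,
        config,
        compute_all=True,
    )
    return RouterOutput(
        token=np.asarray(token, dtype=float).ravel().copy(),
        gates=gates.data.copy(),
        expert_risks=expert_risks.data.copy(),
        risk=risk.item(),
    )


def forward_tensor(
    record: PatientRecord,
    params: dict[str, Tensor],
    config: ModelConfig,
    token_cache: dict[int, Tensor] | None = None,
) -> tuple[Tensor, dict]:
    """Full forward pass building the autodiff graph; returns (risk, aux).

    ``token_cache`` (cancer index -> token node) may be shared across patients
    of one accumulated batch: the control token depends only on the cancer
    index, and gradients accumulate correctly through the shared subgraph.
    """
    pooled, provenance = pool_patient_bag(record)
    if pooled.shape[1] != config.D:
        raise DimensionError(f"bag D={pooled.shape[1]} != config D={config.D}")
    H1, attn, scores, E = amil_forward(pooled, params, return_internals=True)
    # per-cancer linear instance-risk: its mean-pooled Cox readout identifies
    # the sign of "risk-elevating" patch evidence, anchoring attention polarity
    instance_risk = ag.matmul(E, params["amil.probe"][:, record.cancer.index])
    fused, fuse_aux = fuse_forward(H1, record.clinical.values, params, config)
    if token_cache is not None and record.cancer.index in token_cache:
        token = token_cache[record.cancer.index]
    else:
        token = token_forward(record.cancer.onehot, params)
        if token_cache is not None:
            token_cache[record.cancer.index] = token
    risk, gates, expert_risks = route_forward(
        fused, token, record.cancer.index, params, config
    )
    aux = {
        "attn": attn,
        "attn_scores": scores,
        "instance_risk": instance_risk,
        "gates": gates,
        "provenance": provenance,
        "expert_risks": expert_risks,
        **fuse_aux,
    }
    return risk, aux


def model_forward(
    record: PatientRecord, params: dict[str, Tensor], config: ModelConfig
) -> RiskPrediction:
    """Inference-mode forward: deterministic for fixed params and record."""
    risk, aux = forward_tensor(record, params, config)
    return RiskPrediction(
        patient_id=record.patient_id,
        risk=risk.item(),
        attn=aux["attn"].data.copy(),
        attn_provenance=aux["provenance"],
        gates=aux["gates"].data.copy(),
    )


# ----------------------------------------------------------------- checkpoint
CHECKPOINT_VERSION = "1"


def save_checkpoint(
    path: str | Path,
    params: dict[str, Tensor],
    config: ModelConfig,
    cancer_labels: tuple[str, ...] = (),
) -> None:
    """Single-file checkpoint: config + weights + cancer-label map."""
    meta = json.dumps(
        {
            "version": CHECKPOINT_VERSION,
            "config": asdict(config),
            "cancer_labels": list(cancer_labels),
        }
    )
    arrays = {k.replace(".", "__"): v.data for k, v in params.items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path):
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        params = {
            k.replace("__", "."): Tensor(z[k], requires_grad=True)
            for k in z.files
            if k != "__meta__"
        }
    config = ModelConfig(**meta["config"])
    return params, config, tuple(meta["cancer_labels"])
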