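"""Cross-validated training: stratified folds, cancer-balanced batches,
gradient-accumulated AdamW optimization with a cosine learning-rate schedule.

The accumulation contract: however the per-patient forwards are staged, the
Cox risk sets and the ranking pairs always span the full accumulated batch,
so the loss and the parameter gradients are identical to a joint full-batch
computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autograd as ag
from .autograd import Tensor
from .core import Cohort, PatientRecord, ValidationError
from .network import ModelConfig, forward_tensor, init_params
from .objectives import total_loss_tensor

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 20
    batch_patients: int = 256
    weight_decay: float = 1e-2
    lr_min: float = 0.0
    ema_decay: float | None = None   # Polyak weight averaging (e.g. 0.98/step)
    #: weight of the survival loss applied to the mean-pooled instance-risk
    #: probe (a linear per-cancer patch readout whose Cox sign is identified)
    aux_probe_weight: float = 0.3
    #: weight of the pairwise term aligning attention scores with the probe's
    #: (stop-gradient) patch ranking; anchors heatmap polarity, which is
    #: otherwise unidentified under a purely rank-based bag objective
    attn_anchor_weight: float = 0.3
    #: learning-rate multiplier for the router's gate projection; a slow gate
    #: keeps the own-cancer boost decisive while experts specialize
    gate_lr_mult: float = 0.1
    #: independently initialized members trained per fold; with n_init > 1 the
    #: out-of-fold risks are the average of within-fold percentile ranks over
    #: members (risk scales across fits are not comparable, ranks are)
    n_init: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.epochs <= 0 or self.batch_patients <= 0:
            raise ConfigError("lr, epochs and batch_patients must be positive")
        if self.weight_decay < 0 or self.lr_min < 0:
            raise ConfigError("weight_decay and lr_min must be >= 0")


@dataclass
class SplitPlan:
    """Patient -> fold assignment, stratified by cancer type."""

    assignments: dict[str, int]
    k: int
    seed: int

    def fold_of(self, patient_id: str) -> int:
        return self.assignments[patient_id]

    def train_ids(self, fold: int) -> list[str]:
        return [p for p, f in self.assignments.items() if f != fold]

    def val_ids(self, fold: int) -> list[str]:
        return [p for p, f in self.assignments.items() if f == fold]


def stratified_kfold(cohort: Cohort, k: int = 5, seed: int = 0) -> SplitPlan:
    """Within each cancer type, shuffle patients then deal round-robin to folds."""
    if k < 2:
        raise ConfigError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    by_cancer: dict[int, list[str]] = {}
    for p in cohort.patients:
        by_cancer.setdefault(p.cancer.index, []).append(p.patient_id)
    for cancer in sorted(by_cancer):
        ids = sorted(by_cancer[cancer])
        if len(ids) < k:
            warnings.warn(
                f"cancer index {cancer} has only {len(ids)} patients for {k} folds; "
                "best-effort assignment"
            )
        rng.shuffle(ids)
        for i, pid in enumerate(ids):
            assignments[pid] = i % k
    return SplitPlan(assignments=assignments, k=k, seed=seed)


def make_balanced_batches(
    patients: list[PatientRecord],
    batch_patients: int,
    seed: int = 0,
    epoch: int = 0,
) -> list[list[str]]:
    """Batches whose per-cancer counts track the cohort proportions within +-1.

    Patients of each cancer type are shuffled (per epoch, derived from seed)
    and dealt into ceil(N / batch) batches by proportional quota; the final
    batch may be partial.
    """
    K_present = len({p.cancer.index for p in patients})
    if batch_patients < K_present:
        raise ConfigError(
            f"batch_patients={batch_patients} is smaller than the number of "
            f"cancer types present ({K_present})"
        )
    rng = np.random.default_rng((seed, epoch))
    n = len(patients)
    n_batches = int(np.ceil(n / batch_patients))
    by_cancer: dict[int, list[str]] = {}
    for p in patients:
        by_cancer.setdefault(p.cancer.index, []).append(p.patient_id)
    batches: list[list[str]] = [[] for _ in range(n_batches)]
    for cancer in sorted(by_cancer):
        ids = sorted(by_cancer[cancer])
        rng.shuffle(ids)
        n_c = len(ids)
        for b in range(n_batches):
            lo = round(b * n_c / n_batches)
            hi = round((b + 1) * n_c / n_batches)
            batches[b].extend(ids[lo:hi])
    for b in batches:
        rng.shuffle(b)
    return [b for b in batches if b]


def cosine_lr(epoch: int, total_epochs: int, lr: float, lr_min: float = 0.0) -> float:
    """Closed-form cosine annealing: lr at epoch 0, lr_min at epoch == total."""
    t = min(max(epoch, 0), total_epochs) / total_epochs
    return lr_min + 0.5 * (lr - lr_min) * (1.0 + np.cos(np.pi * t))


class AdamW:
    """Decoupled weight-decay Adam over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-2,
                 lr_multipliers: dict[str, float] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.lr_multipliers = lr_multipliers or {}
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def _lr_for(self, name: str) -> float:
        for prefix, mult in self.lr_multipliers.items():
            if name.startswith(prefix):
                return self.lr * mult
        return self.lr

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self._lr_for(k) * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )


def _attn_anchor_loss(scores: Tensor, instance_risk: Tensor, max_pairs: int = 512):
    """Pairwise logistic loss pushing attention scores to rank patches the way
    the instance-risk probe does (probe values taken as constants)."""
    c = instance_risk.data
    n = len(c)
    if n < 2:
        return None
    ii, jj = np.triu_indices(n, k=1)
    swap = c[ii] < c[jj]
    ii[swap], jj[swap] = jj[swap].copy(), ii[swap].copy()
    keep = c[ii] > c[jj]
    ii, jj = ii[keep], jj[keep]
    if len(ii) == 0:
        return None
    if len(ii) > max_pairs:
        sel = np.linspace(0, len(ii) - 1, max_pairs).astype(int)
        ii, jj = ii[sel], jj[sel]
    margins = ag.add(scores[ii], ag.mul(scores[jj], -1.0))
    return ag.tensor_mean(ag.softplus(ag.mul(margins, -1.0)))


def batch_loss_and_grads(
    params: dict[str, Tensor],
    records: list[PatientRecord],
    config: ModelConfig,
    chunk_size: int | None = None,
    aux_probe_weight: float = 0.0,
    attn_anchor_weight: float = 0.0,
) -> tuple[float, dict[str, np.ndarray], dict]:
    """Forward a batch (optionally staged in chunks), compute the joint loss
    over the full batch, backpropagate, and return (loss, grads, info).

    Leaves parameter ``.grad`` fields populated.  The Cox risk sets and
    ranking pairs always cover the whole batch regardless of chunking.  With
    nonzero auxiliary weights the total adds the probe survival loss and the
    attention anchoring term (see TrainConfig).
    """
    if not records:
        raise ValidationError("empty batch")
    for p in params.values():
        p.grad = None
    risk_tensors: list[Tensor] = []
    aux_risk_tensors: list[Tensor] = []
    anchor_terms: list[Tensor] = []
    order = list(range(len(records)))
    chunks = (
        [order]
        if chunk_size is None
        else [order[i : i + chunk_size] for i in range(0, len(order), chunk_size)]
    )
    token_cache: dict[int, Tensor] = {}
    for chunk in chunks:
        for i in chunk:
            risk, aux = forward_tensor(records[i], params, config, token_cache=token_cache)
            risk_tensors.append(ag.reshape(risk, (1,)))
            if aux_probe_weight > 0:
                aux_risk_tensors.append(
                    ag.reshape(ag.tensor_mean(aux["instance_risk"]), (1,))
                )
            if attn_anchor_weight > 0:
                term = _attn_anchor_loss(aux["attn_scores"], aux["instance_risk"])
                if term is not None:
                    anchor_terms.append(ag.reshape(term, (1,)))
    risks = ag.concat(risk_tensors, axis=0)
    times = np.array([r.survival.time for r in records])
    events = np.array([r.survival.event for r in records])
    loss, info = total_loss_tensor(risks, times, events)
    if aux_risk_tensors:
        aux_loss, _ = total_loss_tensor(
            ag.concat(aux_risk_tensors, axis=0), times, events
        )
        info["aux_probe"] = aux_loss.item()
        loss = ag.add(loss, ag.mul(aux_loss, aux_probe_weight))
    if anchor_terms:
        anchor = ag.tensor_mean(ag.concat(anchor_terms, axis=0))
        info["attn_anchor"] = anchor.item()
        loss = ag.add(loss, ag.mul(anchor, attn_anchor_weight))
    ag.backward(loss)
    grads = {k: (np.array(p.grad) if p.grad is not None else np.zeros_like(p.data))
             for k, p in params.items()}
    return loss.item(), grads, info


def accumulate_step(
    params: dict[str, Tensor],
    records: list[PatientRecord],
    config: ModelConfig,
    optimizer: AdamW,
    chunk_size: int | None = None,
    aux_probe_weight: float = 0.0,
    attn_anchor_weight: float = 0.0,
) -> float | None:
    """One optimization step on an accumulated batch.

    All-censored batches are skipped (Cox term undefined; a vacuous step would
    only drift the optimizer state) and return None.
    """
    if all(r.survival.event == 0 for r in records):
        log.warning("all-censored batch of %d patients skipped", len(records))
        return None
    optimizer.zero_grad()
    loss, _, _ = batch_loss_and_grads(
        params, records, config, chunk_size=chunk_size,
        aux_probe_weight=aux_probe_weight, attn_anchor_weight=attn_anchor_weight,
    )
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite training loss {loss}")
    optimizer.step()
    return loss


@dataclass
class FitResult:
    fold_params: dict[int, dict[str, Tensor]]
    oof: pd.DataFrame                     # one out-of-fold prediction per patient
    history: pd.DataFrame                 # per (fold, epoch): loss components, lr
    plan: SplitPlan
    config: ModelConfig
    train_config: TrainConfig


def fit(
    cohort: Cohort,
    plan: SplitPlan,
    config: ModelConfig,
    train_config: TrainConfig,
    chunk_size: int | None = None,
) -> FitResult:
    """Train one model per fold; emit out-of-fold predictions for every patient."""
    from .network import model_forward  # local import to avoid cycle confusion

    by_id = {p.patient_id: p for p in cohort.patients}
    fold_params: dict[int, dict[str, Tensor]] = {}
    oof_rows = []
    hist_rows = []
    for fold in range(plan.k):
        train_records = [by_id[i] for i in plan.train_ids(fold)]
        val_ids = plan.val_ids(fold)
        member_risks: list[np.ndarray] = []
        for member in range(train_config.n_init):
            # member 0 reproduces the single-init stream exactly
            init_seed = ((train_config.seed + 7919 * member) * 1000 + fold) % (2**31)
            batch_seed = (train_config.seed * 100 + fold + 104729 * member) % (2**31)
            params = init_params(config, seed=init_seed)
            opt = AdamW(
                params,
                lr=train_config.lr,
                weight_decay=train_config.weight_decay,
                lr_multipliers={"router.gate": train_config.gate_lr_mult},
            )
            ema = (
                {k: p.data.copy() for k, p in params.items()}
                if train_config.ema_decay is not None
                else None
            )
            for epoch in range(train_config.epochs):
                opt.lr = cosine_lr(
                    epoch, train_config.epochs, train_config.lr, train_config.lr_min
                )
                batches = make_balanced_batches(
                    train_records,
                    train_config.batch_patients,
                    seed=batch_seed,
                    epoch=epoch,
                )
                epoch_losses = []
                for batch_ids in batches:
                    loss = accumulate_step(
                        params, [by_id[i] for i in batch_ids], config, opt,
                        chunk_size=chunk_size,
                        aux_probe_weight=train_config.aux_probe_weight,
                        attn_anchor_weight=train_config.attn_anchor_weight,
                    )
                    if loss is not None:
                        epoch_losses.append(loss)
                        if ema is not None:
                            a = train_config.ema_decay
                            for k, p in params.items():
                                ema[k] = a * ema[k] + (1 - a) * p.data
                hist_rows.append(
                    dict(fold=fold, member=member, epoch=epoch, lr=opt.lr,
                         loss=float(np.mean(epoch_losses)) if epoch_losses else np.nan)
                )
            if ema is not None:
                params = {k: Tensor(v, requires_grad=True) for k, v in ema.items()}
            if member == 0:
                fold_params[fold] = params
            risks = np.array(
                [model_forward(by_id[pid], params, config).risk for pid in val_ids]
            )
            member_risks.append(risks)
        if train_config.n_init == 1:
            oof_risks = member_risks[0]
        else:
            # average within-fold percentile ranks: fits are only comparable
            # on the rank scale
            from scipy.stats import rankdata

            oof_risks = np.mean(
                [rankdata(r) / (len(r) + 1) for r in member_risks], axis=0
            )
        for pid, risk in zip(val_ids, oof_risks):
            rec = by_id[pid]
            oof_rows.append(
                dict(
                    patient_id=pid,
                    fold=fold,
                    risk=float(risk),
                    time=rec.survival.time,
                    event=rec.survival.event,
                    cancer=rec.cancer.label,
                    cancer_index=rec.cancer.index,
                )
            )
    oof = pd.DataFrame(oof_rows).sort_values("patient_id").reset_index(drop=True)
    history = pd.DataFrame(hist_rows)
    return FitResult(
        fold_params=fold_params,
        oof=oof,
        history=history,
        plan=plan,
        config=config,
        train_config=train_config,
    )
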