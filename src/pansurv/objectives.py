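"""Joint survival objective L = L_cox + L_rank.

L_cox is the negative log Breslow partial likelihood averaged over events:
for each event i, the contribution is -(r_i - log Σ_{j: t_j >= t_i} e^{r_j}).
Breslow's approximation handles tied event times (every patient with
t_j >= t_i is in the risk set, ties included).

L_rank is a pairwise logistic surrogate over comparable pairs
P = {(i, j): event_i = 1 and t_i < t_j}: mean of log(1 + exp(-(r_i - r_j))).
It is antitone in every margin r_i - r_j, so minimizing it pushes predicted
risks toward the observed survival ordering.

Both terms are normalized (mean over events / mean over pairs) so they remain
scale-comparable across batch sizes before their unweighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .core import ValidationError


@dataclass
class BatchSurvival:
    """Aligned per-patient risks, times and event indicators for one batch."""

    risks: np.ndarray
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        self.risks = np.asarray(self.risks, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if not (len(self.risks) == len(self.times) == len(self.events)):
            raise ValidationError("risks, times, events must share one length")
        if len(self.risks) < 1:
            raise ValidationError("batch must contain at least one patient")
        if np.any(self.times <= 0):
            raise ValidationError("times must be positive")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValidationError("events must be 0/1")
        if not np.all(np.isfinite(self.risks)):
            raise ValidationError("non-finite risks")


@dataclass
class LossValue:
    value: float
    n_terms: int          # events (cox) or comparable pairs (rank)
    flag: str | None = None

    def __float__(self):
        return self.value


# ------------------------------------------------------------- tensor losses
def cox_nll_tensor(
    risks: Tensor, times: np.ndarray, events: np.ndarray
) -> tuple[Tensor, int]:
    """Breslow partial-likelihood NLL on a risk tensor; returns (loss, n_events)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    event_idx = np.flatnonzero(events == 1)
    if len(event_idx) == 0:
        return Tensor(0.0), 0
    # at_risk[i, j] = 1 if t_j >= t_i, rows restricted to events
    at_risk = (times[None, :] >= times[event_idx, None]).astype(float)
    m = float(np.max(risks.data))
    exp_shift = ag.exp(ag.add(risks, -m))
    lse = ag.add(ag.log(ag.matmul(Tensor(at_risk), exp_shift)), m)   # (n_events,)
    contrib = ag.add(lse, ag.mul(risks[event_idx], -1.0))
    return ag.tensor_mean(contrib), len(event_idx)


def rank_loss_tensor(
    risks: Tensor, times: np.ndarray, events: np.ndarray
) -> tuple[Tensor, int]:
    """Pairwise logistic ranking loss; returns (loss, n_pairs)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    pair_mask = (events[:, None] == 1) & (times[:, None] < times[None, :])
    n_pairs = int(pair_mask.sum())
    if n_pairs == 0:
        return Tensor(0.0), 0
    ii, jj = np.nonzero(pair_mask)
    margins = ag.add(risks[ii], ag.mul(risks[jj], -1.0))
    return ag.tensor_mean(ag.softplus(ag.mul(margins, -1.0))), n_pairs


def total_loss_tensor(
    risks: Tensor, times: np.ndarray, events: np.ndarray
) -> tuple[Tensor, dict]:
    cox, n_events = cox_nll_tensor(risks, times, events)
    rank, n_pairs = rank_loss_tensor(risks, times, events)
    info = {"n_events": n_events, "n_pairs": n_pairs,
            "cox": cox.item(), "rank": rank.item()}
    return ag.add(cox, rank), info


# -------------------------------------------------------------- float losses
def cox_nll(batch: BatchSurvival) -> LossValue:
    """Negative log Breslow partial likelihood, averaged over events."""
    loss, n = cox_nll_tensor(Tensor(batch.risks), batch.times, batch.events)
    return LossValue(loss.item(), n, flag=None if n else "no-events")


def rank_loss(batch: BatchSurvival) -> LossValue:
    """Mean logistic loss over comparable pairs (empty pair set -> 0)."""
    loss, n = rank_loss_tensor(Tensor(batch.risks), batch.times, batch.events)
    return LossValue(loss.item(), n, flag=None if n else "no-pairs")


def total_loss(batch: BatchSurvival) -> LossValue:
    c = cox_nll(batch)
    r = rank_loss(batch)
    flags = [f for f in (c.flag, r.flag) if f]
    return LossValue(c.value + r.value, c.n_terms + r.n_terms,
                     flag=";".join(flags) if flags else None)
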