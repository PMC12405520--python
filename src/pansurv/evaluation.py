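"""Survival evaluation: Harrell's C-index, IPCW time-dependent AUC,
Kaplan-Meier with Greenwood confidence bands, the two-group log-rank test,
median-risk stratification, paired bootstrap model comparison, and the
Mann-Whitney U comparison of per-fold scores.

Comparable-pair convention throughout (Harrell's original): pairs (i, j) with
event_i = 1 and t_i < t_j; risk ties count 0.5; two patients with identical
times and both events are not comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import IntegrityError, ValidationError


# --------------------------------------------------------------- concordance
def harrell_cindex(risks, times, events) -> float | None:
    """Concordant / comparable over Harrell comparable pairs (ties 0.5).

    Returns None (flagged undefined) when there are no comparable pairs.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    comparable = (events[:, None] == 1) & (times[:, None] < times[None, :])
    n_comp = comparable.sum()
    if n_comp == 0:
        warnings.warn("no comparable pairs: C-index undefined")
        return None
    greater = risks[:, None] > risks[None, :]
    equal = risks[:, None] == risks[None, :]
    concordant = (comparable & greater).sum() + 0.5 * (comparable & equal).sum()
    return float(concordant / n_comp)


# -------------------------------------------------------- censoring KM / IPCW
def _km_steps(times, events):
    """Distinct event times with at-risk and event counts."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    t_ev = np.unique(times[events == 1])
    n_at_risk = np.array([(times >= t).sum() for t in t_ev])
    n_events = np.array([((times == t) & (events == 1)).sum() for t in t_ev])
    return t_ev, n_at_risk, n_events


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood 95% CI (log-log)."""

    times: np.ndarray           # distinct event times
    survival: np.ndarray        # S(t) at those times
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """S(t), right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier estimator; variance by Greenwood, CI via log-log transform."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) < 1:
        raise ValidationError("need at least one observation")
    t_ev, n_risk, n_ev = _km_steps(times, events)
    if len(t_ev) == 0:
        return KMCurve(np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0),
                       n=len(times), n_events=0)
    frac = 1.0 - n_ev / n_risk
    S = np.cumprod(frac)
    # Greenwood: var(S) = S^2 * cumsum(d / (n(n-d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n_risk > n_ev, n_ev / (n_risk * (n_risk - n_ev)), np.inf))
        var = S**2 * gw
        # log-log CI: exp(-exp(log(-log S) -+ z * se(log(-log S))))
        se_loglog = np.sqrt(var) / np.abs(S * np.log(S))
    z = stats.norm.ppf(0.975)
    lo = np.empty_like(S)
    hi = np.empty_like(S)
    for i, s in enumerate(S):
        if s <= 0.0 or s >= 1.0 or not np.isfinite(se_loglog[i]):
            lo[i], hi[i] = (s, s) if s in (0.0, 1.0) else (0.0, 1.0)
        else:
            theta = np.log(-np.log(s))
            lo[i] = np.exp(-np.exp(theta + z * se_loglog[i]))
            hi[i] = np.exp(-np.exp(theta - z * se_loglog[i]))
    return KMCurve(
        times=t_ev,
        survival=S,
        ci_lower=np.clip(lo, 0.0, 1.0),
        ci_upper=np.clip(hi, 0.0, 1.0),
        n=len(times),
        n_events=int(events.sum()),
    )


def censoring_survival(times, events) -> KMCurve:
    """KM estimate of the censoring distribution G (events and censorings swapped)."""
    events = np.asarray(events, dtype=int)
    return km_curve(times, 1 - events)


# --------------------------------------------------------- time-dependent AUC
def time_dependent_auc(
    risks, times, events, n_times: int = 4, ipcw: bool = True
) -> tuple[float | None, pd.DataFrame]:
    """Cumulative/dynamic AUC averaged over an evenly spaced time grid.

    The grid is ``n_times`` points evenly spaced between the 20th and 81st
    percentiles of the observed times.  At each grid time t, cases are
    patients with an observed event by t and controls those event-free past
    t; with ``ipcw`` the cases are weighted by 1/G(T_i-), the KM estimate of
    the censoring survival just before their event time.  Grid points with no
    cases or no controls are dropped with a warning.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    lo_t, hi_t = np.percentile(times, [20, 81])
    grid = np.linspace(lo_t, hi_t, n_times) if n_times > 1 else np.array([(lo_t + hi_t) / 2])
    G = censoring_survival(times, events)
    rows = []
    for t in grid:
        cases = (times <= t) & (events == 1)
        controls = times > t
        if cases.sum() == 0 or controls.sum() == 0:
            warnings.warn(f"no cases or no controls at grid time {t:.3g}: dropped")
            rows.append(dict(time=t, auc=np.nan, n_cases=int(cases.sum()),
                             n_controls=int(controls.sum())))
            continue
        if ipcw:
            w = np.array([1.0 / max(G.at(ti - 1e-12), 1e-12) for ti in times[cases]])
        else:
            w = np.ones(int(cases.sum()))
        r_case = risks[cases]
        r_ctrl = risks[controls]
        greater = (r_case[:, None] > r_ctrl[None, :]).astype(float)
        tied = (r_case[:, None] == r_ctrl[None, :]).astype(float)
        num = (w[:, None] * (greater + 0.5 * tied)).sum()
        den = w.sum() * len(r_ctrl)
        rows.append(dict(time=t, auc=float(num / den), n_cases=int(cases.sum()),
                         n_controls=int(controls.sum())))
    per_time = pd.DataFrame(rows)
    valid = per_time["auc"].dropna()
    if valid.empty:
        warnings.warn("all grid times dropped: time-dependent AUC undefined")
        return None, per_time
    return float(valid.mean()), per_time


# ------------------------------------------------------------------ log-rank
def logrank_test(group_labels, times, events) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, two-sided p)."""
    group_labels = np.asarray(group_labels)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.unique(group_labels)
    if len(groups) != 2:
        raise ValidationError(f"log-rank needs exactly two groups, got {len(groups)}")
    in_a = group_labels == groups[0]
    if in_a.sum() == 0 or (~in_a).sum() == 0:
        warnings.warn("a group has zero at-risk mass: log-rank undefined")
        return np.nan, np.nan
    t_ev = np.unique(times[events == 1])
    O_minus_E = 0.0
    V = 0.0
    for t in t_ev:
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & in_a).sum()
        O_minus_E += d_a - d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = O_minus_E**2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------- risk split
def median_risk_split(risks) -> np.ndarray:
    """High/low grouping at the median risk (>= median -> 'high').

    Uses the standard sample median (mean of the two middle order statistics
    for even n), so an even, tie-free cohort splits exactly in half; for odd
    n the middle patient lands in the high-risk group.  All-identical risks
    yield a degenerate split (everything 'high') and a warning.
    """
    risks = np.asarray(risks, dtype=float)
    if len(risks) < 2:
        raise ValidationError("need at least two patients to split")
    labels = np.where(risks >= np.median(risks), "high", "low")
    if len(np.unique(labels)) == 1:
        warnings.warn("degenerate median split: all risks on one side")
    return labels


# ----------------------------------------------------------------- bootstrap
def bootstrap_ci_and_ztest(
    risks_a, risks_b, times, events, n_boot: int = 1000, seed: int = 0
) -> dict:
    """Paired bootstrap over patients: per-model C-index 95% CIs and a
    two-sided z-test on the replicate-wise C-index difference.

    The same resample indices feed both models (paired design).  Replicates
    without comparable pairs are redrawn.
    """
    risks_a = np.asarray(risks_a, dtype=float)
    risks_b = np.asarray(risks_b, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (len(risks_a) == len(risks_b) == len(times) == len(events)):
        raise ValidationError("risk vectors must align to the same patients")
    rng = np.random.default_rng(seed)
    n = len(times)
    ca = np.empty(n_boot)
    cb = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            c1 = harrell_cindex(risks_a[idx], times[idx], events[idx])
            if c1 is None:
                redrawn += 1
                continue
            c2 = harrell_cindex(risks_b[idx], times[idx], events[idx])
            break
        ca[b], cb[b] = c1, c2
    delta = ca - cb
    sd = delta.std(ddof=1)
    if sd == 0:
        z, p = 0.0, 1.0
    else:
        z = delta.mean() / sd
        p = float(2 * stats.norm.sf(abs(z)))
    return dict(
        ci_a=(float(np.percentile(ca, 2.5)), float(np.percentile(ca, 97.5))),
        ci_b=(float(np.percentile(cb, 2.5)), float(np.percentile(cb, 97.5))),
        mean_a=float(ca.mean()),
        mean_b=float(cb.mean()),
        z=float(z),
        p=p,
        n_boot=n_boot,
        n_redrawn=redrawn,
    )


def mannwhitney_compare(scores_a, scores_b) -> tuple[float, float]:
    """Mann-Whitney U comparison of per-fold scores (exact p for small untied
    samples, midrank/asymptotic with ties); returns (U, two-sided p)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if len(scores_a) == 0 or len(scores_b) == 0:
        raise ValidationError("score lists must be nonempty")
    ties = len(np.unique(np.concatenate([scores_a, scores_b]))) < len(scores_a) + len(scores_b)
    method = "asymptotic" if ties else "exact"
    res = stats.mannwhitneyu(scores_a, scores_b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# --------------------------------------------------------------- aggregation
@dataclass
class EvalReport:
    c_index: float | None
    td_auc: float | None
    td_auc_per_time: pd.DataFrame
    km_high: KMCurve | None
    km_low: KMCurve | None
    logrank_chi2: float
    logrank_p: float
    n_patients: int
    n_events: int
    per_cancer: dict[str, "EvalReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(
            c_index=self.c_index,
            td_auc=self.td_auc,
            logrank_chi2=self.logrank_chi2,
            logrank_p=self.logrank_p,
            n_patients=self.n_patients,
            n_events=self.n_events,
        )
        if self.per_cancer:
            d["per_cancer"] = {k: v.to_dict() for k, v in self.per_cancer.items()}
        return d


def evaluate_predictions(
    risks, times, events, n_times: int = 4, ipcw: bool = True
) -> EvalReport:
    """All pooled metrics for one aligned prediction set."""
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    c = harrell_cindex(risks, times, events)
    auc, per_time = time_dependent_auc(risks, times, events, n_times=n_times, ipcw=ipcw)
    km_hi = km_lo = None
    chi2, p = np.nan, np.nan
    if len(risks) >= 2 and len(np.unique(risks)) > 1:
        labels = median_risk_split(risks)
        if len(np.unique(labels)) == 2:
            km_hi = km_curve(times[labels == "high"], events[labels == "high"])
            km_lo = km_curve(times[labels == "low"], events[labels == "low"])
            chi2, p = logrank_test(labels, times, events)
    return EvalReport(
        c_index=c,
        td_auc=auc,
        td_auc_per_time=per_time,
        km_high=km_hi,
        km_low=km_lo,
        logrank_chi2=chi2,
        logrank_p=p,
        n_patients=len(risks),
        n_events=int(events.sum()),
    )


def fold_rank_calibrate(oof: pd.DataFrame) -> pd.DataFrame:
    """Replace each fold's risks by their within-fold percentile ranks.

    Cross-validated risk scores come from different fitted models whose
    outputs are only identified up to a monotone transform (the survival
    losses are translation-invariant), so pooling raw scores mixes
    incompatible scales and deflates rank-based metrics.  Within-fold
    percentile ranks are the scale-free common currency.
    """
    out = oof.copy()
    for _, grp in out.groupby("fold"):
        ranks = stats.rankdata(grp["risk"].values)
        out.loc[grp.index, "risk"] = ranks / (len(grp) + 1)
    return out


def aggregate_cv(
    oof: pd.DataFrame,
    by_cancer: bool = True,
    n_times: int = 4,
    calibrate_folds: bool = False,
) -> EvalReport:
    """Pool out-of-fold predictions and compute overall + per-cancer metrics.

    ``oof`` must contain exactly one row per patient with columns
    patient_id, risk, time, event and (for the per-cancer breakdown) cancer.
    With ``calibrate_folds`` (requires a ``fold`` column) risks are replaced
    by within-fold percentile ranks before pooling; see
    :func:`fold_rank_calibrate`.
    """
    if oof["patient_id"].duplicated().any():
        dupes = oof.loc[oof["patient_id"].duplicated(), "patient_id"].tolist()
        raise IntegrityError(f"duplicate out-of-fold predictions for {dupes}")
    if calibrate_folds:
        oof = fold_rank_calibrate(oof)
    report = evaluate_predictions(
        oof["risk"].values, oof["time"].values, oof["event"].values, n_times=n_times
    )
    if by_cancer and "cancer" in oof.columns:
        for cancer, grp in oof.groupby("cancer"):
            if len(grp) < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report.per_cancer[str(cancer)] = evaluate_predictions(
                    grp["risk"].values, grp["time"].values, grp["event"].values,
                    n_times=n_times,
                )
    return report
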