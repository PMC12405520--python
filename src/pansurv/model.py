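"""Model / Results surface for the pancancer survival network.

Follows the fitted-model convention of the statistical-modelling ecosystem:
``PancancerSurvivalModel`` is constructed from a cohort (or a manifest plus a
bag directory), ``fit()`` runs stratified cross-validated training and returns
a ``PancancerSurvivalResults`` carrying the out-of-fold risk predictions,
per-fold checkpoints, the evaluation report and a printable summary.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Cohort, PatientRecord
from .evaluation import EvalReport, aggregate_cv
from .io import attach_bags, read_manifest
from .network import (
    ModelConfig,
    RiskPrediction,
    model_forward,
    save_checkpoint,
)
from .trainer import FitResult, SplitPlan, TrainConfig, fit, stratified_kfold


class PancancerSurvivalModel:
    """Survival model over a multicancer cohort of feature bags + clinical data.

    Parameters
    ----------
    cohort
        A fully loaded :class:`~pansurv.core.Cohort` (bags attached).
    config
        Network configuration; ``D`` and ``K`` default to the cohort's.
    """

    def __init__(self, cohort: Cohort, config: ModelConfig | None = None):
        self.cohort = cohort
        if config is None:
            config = ModelConfig(D=cohort.D, K=cohort.K)
        if config.D != cohort.D or config.K != cohort.K:
            config = replace(config, D=cohort.D, K=cohort.K)
        self.config = config

    @classmethod
    def from_manifest(
        cls,
        manifest_path: str | Path,
        bag_dir: str | Path,
        config: ModelConfig | None = None,
    ) -> "PancancerSurvivalModel":
        cohort, _ = read_manifest(manifest_path)
        cohort = attach_bags(cohort, bag_dir)
        return cls(cohort, config)

    def fit(
        self,
        train_config: TrainConfig | None = None,
        n_folds: int = 5,
        seed: int = 0,
        plan: SplitPlan | None = None,
    ) -> "PancancerSurvivalResults":
        """Stratified k-fold training; every patient gets exactly one
        out-of-fold risk prediction."""
        train_config = train_config or TrainConfig(seed=seed)
        if plan is None:
            plan = stratified_kfold(self.cohort, k=n_folds, seed=seed)
        result = fit(self.cohort, plan, self.config, train_config)
        return PancancerSurvivalResults(self, result)


class PancancerSurvivalResults:
    """Fitted cross-validation results."""

    def __init__(self, model: PancancerSurvivalModel, fit_result: FitResult):
        self.model = model
        self._fit = fit_result

    # ------------------------------------------------------------ accessors
    @property
    def oof(self) -> pd.DataFrame:
        """Out-of-fold predictions: patient_id, fold, risk, time, event, cancer."""
        return self._fit.oof

    @property
    def history(self) -> pd.DataFrame:
        return self._fit.history

    @property
    def fold_params(self):
        return self._fit.fold_params

    @property
    def plan(self) -> SplitPlan:
        return self._fit.plan

    # ----------------------------------------------------------- operations
    def evaluate(
        self, by_cancer: bool = True, n_times: int = 4, calibrate_folds: bool = True
    ) -> EvalReport:
        """Pooled out-of-fold evaluation (C-index, td-AUC, KM, log-rank).

        By default each fold's risks are rank-calibrated before pooling,
        since fold models' outputs are only identified up to monotone
        transforms (see :func:`pansurv.evaluation.fold_rank_calibrate`).
        """
        return aggregate_cv(
            self.oof, by_cancer=by_cancer, n_times=n_times,
            calibrate_folds=calibrate_folds,
        )

    def predict(self, record: PatientRecord, fold: int | None = None) -> RiskPrediction:
        """Risk for a (new) patient; fold-ensemble mean risk unless a fold is
        pinned.  Attention/gates come from the first fold model when ensembling."""
        if fold is not None:
            return model_forward(record, self.fold_params[fold], self.model.config)
        preds = [
            model_forward(record, params, self.model.config)
            for params in self.fold_params.values()
        ]
        first = preds[0]
        return RiskPrediction(
            patient_id=record.patient_id,
            risk=float(np.mean([p.risk for p in preds])),
            attn=first.attn,
            attn_provenance=first.attn_provenance,
            gates=first.gates,
        )

    def attention(self, record: PatientRecord, fold: int | None = None):
        """Per-patch attention weights with (slide_id, row) provenance."""
        pred = self.predict(record, fold=fold if fold is not None else 0)
        return pred.attn, pred.attn_provenance

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fold, params in self.fold_params.items():
            save_checkpoint(
                out_dir / f"fold{fold}.npz",
                params,
                self.model.config,
                cancer_labels=self.model.cohort.cancer_labels,
            )
        self.oof.to_csv(out_dir / "oof_predictions.tsv", sep="\t", index=False)
        self.history.to_csv(out_dir / "training_history.tsv", sep="\t", index=False)

    def summary(self) -> str:
        """Printable summary of the fitted cross-validation."""
        report = self.evaluate()
        lines = [
            "Pancancer survival model — cross-validated results",
            "=" * 52,
            f"patients: {report.n_patients}    events: {report.n_events}"
            f"    folds: {self._fit.plan.k}",
            f"cancer types ({self.model.cohort.K}): "
            + ", ".join(self.model.cohort.cancer_labels),
            "",
            f"overall C-index:          {report.c_index:.4f}"
            if report.c_index is not None
            else "overall C-index:          undefined",
            f"mean time-dependent AUC:  {report.td_auc:.4f}"
            if report.td_auc is not None
            else "mean time-dependent AUC:  undefined",
            f"log-rank (median split):  chi2={report.logrank_chi2:.3f}, "
            f"p={report.logrank_p:.3g}",
            "",
            "per-cancer C-index:",
        ]
        for label, sub in sorted(report.per_cancer.items()):
            c = f"{sub.c_index:.4f}" if sub.c_index is not None else "undef"
            lines.append(
                f"  {label:<8} n={sub.n_patients:<5} events={sub.n_events:<5} C={c}"
            )
        return "\n".join(lines)
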