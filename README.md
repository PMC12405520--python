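# pansurv

Pancancer survival modelling from whole-slide image feature bags and routine
clinical variables.

Digitized H&E slides carry prognostic signal, but gigapixel images cannot be
fed to a model directly: each slide is tiled into thousands of 224x224
patches, every patch is embedded by a (pluggable) foundation-model encoder,
and the slide becomes an N x D *feature bag*. `pansurv` turns a multicancer
cohort of such bags — plus age, sex and tumor stage — into patient-level risk
scores with a single unified model:

1. **Attention multiple-instance learning** pools each patient's patches into
   a slide summary H1 through gated attention (softmax of
   `w'(tanh(EV) ⊙ σ(EU))`), exposing per-patch attention for heatmaps.
2. **Cross-attention fusion** projects H1 and the clinical vector C into a
   shared latent space, splits each into sub-tokens, and attends in both
   directions (A_c→h, A_h→c) before fusing.
3. A **cancer-aware mixture-of-experts router** turns the cancer-type one-hot
   into a control token, boosts the own-cancer gate logit by ln K, keeps the
   top-k experts after softmax, and outputs the gated sum of expert risks.

Training minimizes `L = L_cox + L_rank`: the negative log Breslow partial
likelihood `-(r_i - log Σ_{j: t_j ≥ t_i} e^{r_j})` averaged over events, plus
a pairwise logistic ranking loss `log(1 + e^{-(r_i - r_j)})` over comparable
pairs (event_i = 1, t_i < t_j), with cancer-balanced batches, gradient
accumulation whose risk sets always span the full batch, AdamW and a cosine
learning-rate schedule, in stratified k-fold cross-validation.

The evaluation module implements the full protocol: Harrell's C-index,
IPCW time-dependent AUC averaged over a 20th-81st percentile time grid,
Kaplan-Meier curves with Greenwood 95% bands, the two-sided log-rank test at
the median-risk split, paired bootstrap confidence intervals and z-tests, and
exact Mann-Whitney comparison of per-fold scores.

A synthetic cohort generator (`pansurv.synthetic`) produces multicancer
cohorts with known ground truth — informative patch subpopulations whose
prevalence drives an exponential proportional hazard together with clinical
covariates — so the entire pipeline is testable without any external data.
See `docs/methods.md` for the model, the generator and every numerical
choice.

The whole stack is pure scientific Python (numpy/scipy/pandas + h5py for bag
containers); the network runs on a small bundled reverse-mode autodiff
engine, so no deep-learning framework is required.

## Worked example

```python
from pansurv import (PancancerSurvivalModel, ModelConfig, TrainConfig,
                     SimConfig, simulate_cohort, oracle_cindex)

cohort, truth = simulate_cohort(SimConfig(K=3, n_per_type=200, D=32, seed=0))
model = PancancerSurvivalModel(
    cohort,
    ModelConfig(D=32, K=3, d_slide=64, d=64, attn_hidden=32, expert_hidden=32),
)
results = model.fit(
    TrainConfig(lr=2e-3, epochs=15, batch_patients=64, weight_decay=5e-2,
                ema_decay=0.98, seed=0),
    n_folds=5, seed=0,
)
print(results.summary())
print("oracle C-index:", round(oracle_cindex(truth, cohort), 4))
```

```
Pancancer survival model — cross-validated results
====================================================
patients: 600    events: 401    folds: 5
cancer types (3): BLCA, BRCA, CESC

overall C-index:          0.7667
mean time-dependent AUC:  0.8561
log-rank (median split):  chi2=216.028, p=6.65e-49

per-cancer C-index:
  BLCA     n=200   events=128   C=0.7606
  BRCA     n=200   events=137   C=0.7640
  CESC     n=200   events=136   C=0.7721
oracle C-index: 0.7916
```

Every patient receives exactly one out-of-fold risk; the pooled C-index of
0.77 against an oracle ceiling of 0.79 (the concordance of the *true*
log-hazards, bounded away from 1 by outcome noise) says the model recovers
most of the recoverable signal on this small cohort. The log-rank p-value
shows the median-risk split separates survival sharply. `results.oof` holds
the prediction table, `results.predict(record)` scores new patients, and
`results.attention(record)` returns per-patch attention with slide/row
provenance for heatmaps (`pansurv.interpret`).

A command line wraps the same pipeline:

```bash
pansurv simulate --out run/sim --k 3 --n-per-type 200 --dim 32 --seed 0
pansurv train --manifest run/sim/manifest.tsv --bags run/sim/bags --out run/fit --seed 0
pansurv evaluate --predictions run/fit/oof_predictions.tsv --out run/report
pansurv heatmap --bag run/sim/bags/BLCA-0000-s0.h5 --checkpoint run/fit/fold0.npz \
    --slide-thumb thumb.png --out heatmap.png
```

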