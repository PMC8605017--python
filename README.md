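# ctdyn

Tumor-informed ctDNA MRD calling, landmark survival analysis, and joint
modeling of longitudinal log-ctDNA with time-to-recurrence for resected
NSCLC-style cohorts — including individualized dynamic recurrence-risk
prediction and censoring-aware model evaluation.

## What is in the box

| module | contents |
|---|---|
| `ctdyn.splines` | natural cubic spline basis (df=2 default) with closed-form slope and running integral |
| `ctdyn.synthetic` | cohort generator (spline trajectories, trajectory-linked hazards via cumulative-hazard inversion, quarterly visits, MAR dropout) and a UMI read-family simulator |
| `ctdyn.mrd` | SSCS/DCS duplex consensus construction, exact-binomial background-error polishing, tissue thresholds, tumor-informed positivity, the `ln(meanVAF+1e-6)-ln(1e-6)` level transform |
| `ctdyn.survival` | Kaplan–Meier (Greenwood), k-sample log-rank, Cox PH (Efron/Breslow, Newton–Raphson, Breslow baseline), landmark ctDNA-status classification, lead-time analysis with exact tie-aware signed-rank |
| `ctdyn.lmm` | spline linear mixed model (profiled ML, empirical-Bayes modes) |
| `ctdyn.jointmodel` | shared-random-effects joint model, three association structures (current value / +slope / +cumulative AUC), pseudo-adaptive Gauss–Hermite marginal likelihood with analytic gradient, `map_ml` and blockwise-Metropolis `mcmc` engines, association-structure comparison |
| `ctdyn.prediction` | conditional recurrence-free probabilities π(u\|t) with percentile bands (MC over random-effects posterior × parameter draws), plus landmark-Cox and static-Cox comparators |
| `ctdyn.evaluation` | time-dependent AUROC and prediction error with model-based weighting of in-window censoring, repeated stratified k-fold CV, LOOCV Hosmer–Lemeshow with KM-observed probabilities, paired Wilcoxon model comparison |
| `ctdyn.io`, `ctdyn.cli`, `ctdyn.pipeline` | CSV/TSV/YAML schemas with provenance headers, `ctdyn` CLI, end-to-end pipeline |

Time unit is days from surgery; month-denominated landmarks convert at
30.44 d/month (landmark 8 months; horizons 12 and 15 months by default).

## CLI

```sh
ctdyn simulate --seed 1 --n-subjects 150 --outdir out
ctdyn survival --subjects out/subjects.csv --longitudinal out/longitudinal.csv --outdir out
ctdyn fit-joint --subjects out/subjects.csv --longitudinal out/longitudinal.csv \
    --association value+auc --out out/fit.json
ctdyn predict --fit out/fit.json --history subject.csv --horizons 365,456
ctdyn mrd call --tumor-tsv tumor.tsv --plasma-families fams.tsv \
    --background-db db.tsv --alpha 0.01
ctdyn run --seed 1 --outdir out      # full pipeline incl. CV evaluation
```

All outputs carry the package version, seed and config hash in `#` header
comments.

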