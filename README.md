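# gipca — gait-initiation kinetics, bootstrapped PCA and unsupervised classification

`gipca` implements an analysis chain for classifying healthy and
Parkinsonian participants from force-plate recordings of **gait initiation
(GI)** — the transient between quiet standing and steady walking.  It is
aimed at movement scientists and biomedical engineers who record GI trials
on a single force plate and want an unsupervised, small-cohort-friendly
classification methodology, plus a synthetic-data generator to validate the
whole chain.

## The method

1. **Kinetics.** Each trial (3 forces + 3 moments at 500 Hz) is low-pass
   filtered (zero-phase 2nd-order Butterworth, 10 Hz).  The centre of
   pressure is `COP_x = -My/Fz`, `COP_y = Mx/Fz`; the centre-of-mass
   acceleration follows Newton's second law (`a = F/m`) and is integrated
   to velocity with `v(t0) = 0`.  Four landmarks — GI onset `t0`, heel-off
   `HO`, toe-off `TO`, heel contact `HC` — are detected from the COP and
   vertical-force traces, and 11 variables are extracted per participant:
   the ML/AP anticipatory-postural-adjustment (APA) durations, the AP/ML
   COP shifts, the AP COM velocity at HO/TO/HC, the ML COM velocity at
   HO/TO, the foot-lift time and the vertical force peak at HC.

2. **PCA.** The mixed-unit feature table is z-scored and decomposed into
   principal components (correlation-matrix PCA via SVD); the number of
   retained components is the smallest k whose cumulative explained
   variance reaches a threshold (default 99.9%).

3. **Bootstrap.** Each group's mean score vector is bootstrapped
   (participants resampled with replacement, B = 10,000 by default).  The
   resulting mean-clouds concentrate at rate 1/√n, so their 95% confidence
   ellipses `(x-c)ᵀS⁻¹(x-c) ≤ χ²₂(0.95)` are far tighter than the raw-score
   ellipses.

4. **Overlap and classification.** Cloud separation is quantified by the
   Jaccard coefficient `J = |A∩B| / |A∪B|`, discretised by 95%-ellipse
   membership of the pooled cloud points; a two-component full-covariance
   Gaussian mixture (EM, implemented here) then classifies the pooled
   clouds without labels, and clusters are matched to groups by optimal
   assignment before tabulating the confusion matrix.

Because real GI cohorts are rarely shareable, `gipca.synthetic` generates
both feature-table cohorts (two multivariate-normal groups with a
three-factor correlation structure and a PD-like mean shift) and raw
force-plate trials with known ground truth, so every stage is testable end
to end.

## Worked example

```bash
gipca simulate --seed 8 --out demo --effect-scale 1.2
printf 'bootstrap.B = 10000\n' > demo/run.cfg
gipca run --features demo/cohort.csv --config demo/run.cfg --seed 8 --out demo/out
```

prints

```
PC1/PC2: J = 0.095, accuracy = {"control": 95.91, "pd": 96.95}
PC2/PC3: J = 0.001, accuracy = {"control": 98.77, "pd": 99.92}
```

i.e. for this 10+10 cohort the two bootstrapped mean-score clouds overlap
at J = 9.5% in the PC1/PC2 plane (and are essentially disjoint in PC2/PC3),
and the unsupervised mixture recovers the true group of 96–100% of the
pooled cloud points per group.  `demo/out/` contains `report.json` (config
echo, explained variance, simplified loadings, GMM parameters),
`confusion_pc12.csv`, `confusion_pc23.csv`, `cloud_means.csv` and
`pca_model.json`.  The same pipeline runs from raw trials:
`gipca run --trials-dir <dir> --mass 70 ...` (trial CSVs with columns
`t,Fx,Fy,Fz,Mx,My,Mz`).

The library surface mirrors the chain: `simulate_cohort` / `simulate_trial`,
`extract_features`, `fit_pca` / `project`, `bootstrap_means` /
`confidence_ellipse` / `jaccard_overlap`, `fit_gmm` / `classify` /
`align_and_confuse`, and `run_pipeline`.

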