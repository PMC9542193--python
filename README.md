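# comfnet

Source-space EEG functional brain networks and questionnaire psychometrics
for passenger-comfort studies.

## The problem

Riding comfort in transport cabins (high-speed rail in particular) is
usually measured by self-report alone. A stronger design pairs a
multi-item visual-analog questionnaire with EEG recorded during the ride,
asks which cabin factors drive overall comfort, and looks for the
network-level brain signature that separates comfortable from
uncomfortable states. `comfnet` implements both analysis tracks as a
tested, reusable Python package:

* **EEG → source networks.** Sensor conditioning (re-reference, resample,
  zero-phase 0.01–40 Hz band-pass, 50 Hz notch), epoching and artifact
  rejection, wavelet-packet extraction of the five canonical bands
  (delta/theta/alpha/beta/gamma), a standardized minimum-norm (sLORETA-type)
  inverse `T = Kᵀ(KKᵀ + αH)⁺` with per-source standardization
  `√([TK]_ll)`, aggregation to 95 AAL-labelled regions, and phase-locking
  connectivity

  `PLV = (1/N) |Σₙ exp(j(φₓ(tₙ) − φᵧ(tₙ)))|`

  between all region pairs. Each 95×95 matrix is proportionally
  thresholded over the 10–38 % density sweep (step 4 %, eight levels) and
  summarized by graph indices — clustering coefficient CC (Onnela,
  weighted), assortativity AC (Newman), global efficiency GE, path length,
  small-worldness σ, degree, betweenness — integrated over the sweep
  (trapezoidal AUC) and compared between comfort states with paired
  t-tests; per-region tests screen for key brain nodes.
* **Questionnaire psychometrics.** For the 9-item −50..50 VAS instrument:
  Cronbach's α, corrected item-total correlations, α-if-item-deleted, KMO
  and Bartlett sphericity, PCA + varimax factor analysis with the
  0.5-loading validity rule, and a significance-masked Spearman matrix.

Field data of this kind are typically unreleased, so a first-class
synthetic module generates every input — phase-coupled regional
oscillators through a toy lead field, factor-structured questionnaire
tables, reference graphs — with seeded, bit-reproducible output. See
`docs/methods.md` for the models and all numerical choices.

## Worked example

One simulated "uncomfortable" subject (focal coupling 0.8 over a 20-region
active set, diffuse coupling 0.25), connectivity from ground-truth phases,
metrics over the density sweep:

```python
from comfnet import (CohortSpec, generate_cohort_phases, plv_from_phases,
                     build_ensemble, global_metrics_table, global_auc)

spec = CohortSpec(n_subjects=2, coupling_within=0.8, coupling_global=0.25,
                  active_regions=tuple(range(20)), n_epochs=10, seed=1)
phases = generate_cohort_phases(spec)[0]          # epochs x 95 x samples
plv = plv_from_phases(phases)                     # 95 x 95 in [0, 1]
table = global_metrics_table(build_ensemble(plv))
print(table.round(3).to_string(index=False))
print({k: round(v, 4) for k, v in global_auc(table).items()})
```

```
 sparsity    cc    ac    ge   cpl
     0.10 0.334 0.720 0.277 3.379
     0.14 0.398 0.408 0.353 3.059
     0.18 0.424 0.251 0.392 2.764
     0.22 0.430 0.133 0.423 2.580
     0.26 0.438 0.099 0.451 2.444
     0.30 0.447 0.090 0.468 2.345
     0.34 0.471 0.055 0.490 2.287
     0.38 0.472 0.049 0.511 2.235
{'cc': 0.1204, 'ac': 0.0568, 'ge': 0.1189, 'cpl': 0.7315}
```

CC and GE rise with density (more and stronger retained edges shorten
paths); AC starts high — the coupled clique is strongly assortative at
10 % density — and dilutes as weaker edges enter. The AUC row is the
threshold-free summary used in group comparisons.

Questionnaire battery on 500 simulated respondent-windows:

```python
from comfnet import generate_questionnaire, cronbach_alpha, efa_varimax, spearman_matrix

tbl = generate_questionnaire(500, seed=1)
rep = efa_varimax(tbl, n_factors=2)
rho, p, masked = spearman_matrix(tbl)
print("alpha", round(cronbach_alpha(tbl), 3))
print("KMO", round(rep.kmo, 3))
print(rep.loadings.round(2))
```

```
alpha 0.799
KMO 0.841
                        factor_1  factor_2
Overall comfort             0.90      0.16
Emotion value               0.89      0.05
Emotion arousal             0.69     -0.05
Static comfort              0.91      0.08
Noise comfort               0.22      0.78
Vibration comfort           0.26      0.75
Aural pressure comfort      0.30      0.70
Visual comfort             -0.13      0.70
Thermal comfort            -0.14      0.78
```

The α ≈ 0.8 indicates good internal consistency; every item loads > 0.5
on exactly one of the two rotated components (affective/seat vs.
cabin-environment), and the overall-comfort item correlates most with
static comfort (ρ ≈ 0.79) and emotional valence (ρ ≈ 0.78), with visual
and thermal comfort near zero — the planted structure of the generator.

The full chain (simulate → preprocess → source → connect → network →
metrics → stats → psychometrics) runs from one command and writes CSV
outputs plus a manifest with config, digests and all warnings:

```bash
comfnet run-all --seed 0 --out-dir results/demo
```

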