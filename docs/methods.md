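# Methods

This note documents the models, numerical choices and known limitations of
`comfnet`. It is the reference for *why* the defaults are what they are; the
README covers *how* to run things.

## Scientific setting

The package analyses how riding comfort is reflected in brain activity. Two
data tracks are covered:

1. **EEG track.** Multichannel scalp EEG is conditioned, split into the five
   canonical bands (delta 1–3, theta 4–7, alpha 8–13, beta 14–30, gamma
   31–64 Hz), projected into source space with a standardized minimum-norm
   (sLORETA-type) inverse, and averaged into 95 anatomically labelled
   regions. Phase-locking values between all region pairs give a 95×95
   functional connectivity matrix per subject and comfort state. Each matrix
   is proportionally thresholded over a density sweep (10–38 % in 4 % steps)
   and graph indices — weighted clustering coefficient (CC), degree
   assortativity (AC), global efficiency (GE), characteristic path length,
   small-worldness σ, node degree, betweenness — are integrated over the
   sweep (trapezoidal AUC) and compared between comfortable and
   uncomfortable states with paired t-tests. Per-region tests on nodal AUCs
   screen for "key" brain nodes.
2. **Questionnaire track.** A 9-item visual-analog (−50..50) instrument
   (overall comfort, emotional valence and arousal, static/seat comfort,
   and five cabin-environment comforts) is vetted with Cronbach's alpha,
   corrected item-total correlations, alpha-if-item-deleted, KMO and
   Bartlett sphericity, PCA + varimax factor analysis with the 0.5-loading
   validity rule, and a significance-masked Spearman correlation matrix.

Field recordings of this kind are generally not shared, so a seeded
synthetic-data module generates every input and defines the study
conditions under which the package is validated.

## Synthetic cohorts

Each region carries a unit-amplitude oscillation at the band-centre
frequency `f_c` with a Wiener phase offset (step SD 0.1 rad/sample at
250 Hz). Two shared Wiener processes impose coupling:

```
base_i  = (1 − c_g)·W_i + c_g·W_global          (all regions)
phase_i = (1 − c_w)·base_i + c_w·W_active       (active set only)
```

`c_g` (`coupling_global`) is a diffuse, cortex-wide synchronization level;
`c_w` (`coupling_within`) is focal hyper-coupling within a designated
active set (default 20 of 95 regions). Sensor data are `gain @ sources`
plus i.i.d. Gaussian channel noise; every source of a region carries the
region signal. The step SD makes independent phases decorrelate within a
2 s epoch while keeping each oscillator narrow-band around its carrier.

The two simulated comfort states differ in both knobs: comfortable
(c_w = 0.2, c_g = 0.05) vs. uncomfortable (c_w = 0.8, c_g = 0.25). The
diffuse component is essential for reproducing the reported direction of
the group contrast: under proportional thresholding the retained edge
count is fixed, so a purely focal coupling increase concentrates the edge
budget inside the active clique, starves the periphery, and *lowers*
global efficiency. A diffuse increase raises all retained weights, giving
the observed pattern — greater CC, AC and GE AUC under discomfort — which
matches the mechanism usually invoked (broadly stronger inter-regional
connections under stress/discomfort, plus focal emotion-circuit
hyper-coupling).

Default cohort geometry used in the validation studies: 20 subjects,
64 channels, 190 sources (2 per region), 250 Hz, ten 2 s epochs per
condition, beta band. Epoch length and epoch count are free parameters;
no canonical values exist for them, and 2 s × 10 keeps a single cohort
tractable while leaving ≈450 interior samples per epoch for phase
estimation.

What the generator does *not* emulate: 1/f background spectra, ocular or
muscle artifacts, spatially correlated sensor noise, volume-conductor head
geometry (the lead field is a random full-row-rank matrix with unit-norm
columns). Consequently, passing tests show the *pipeline* behaves
correctly under its assumptions — they say nothing about robustness to
realistic artifact structure.

## Preprocessing

* Common-average re-reference (applied before filtering), polyphase
  resampling, 4th-order Butterworth band-pass 0.01–40 Hz and a Q = 30 IIR
  notch at 50 Hz, all zero-phase (`filtfilt`).
* Epochs are 2 s, non-overlapping, grouped into questionnaire windows;
  trailing partial epochs are dropped.
* Artifact rule: reject an epoch when any channel's peak-to-peak exceeds
  100 µV (configurable). Simple, deterministic, and adequate for synthetic
  data; it is not a substitute for ICA-based cleaning on real recordings.
* Band extraction reconstructs the signal from wavelet-packet terminal
  nodes whose nominal support intersects the band. The decomposition level
  is the smallest whose terminal bandwidth (`fs / 2^(level+1)`) resolves
  the 2 Hz-wide delta band — level 6 at 250 Hz. The default wavelet is
  **Daubechies-8**: at this depth db4's transition bands leak ≈18 % of the
  energy of an in-band beta tone out of the selected nodes, failing the
  ≥90 % retention requirement, while db8 retains ≈93 % and suppresses
  out-of-band tones below 1 %. Edge effects make repeated extraction
  non-idempotent at the ≈1 % level for 2 s epochs (below 0.2 % for 8 s).
* Comfort labelling: sign of the window's overall-comfort VAS rating, with
  a configurable neutral exclusion band (default 0). Gamma (31–64 Hz)
  extraction on data low-passed at 40 Hz is allowed but warns — the band
  definition and the acquisition filter are mutually inconsistent, and the
  upper band half carries no signal.

## Source imaging

Fixed-orientation (scalar) sources. With `K` the average-reference-centred
lead field and `H = I − 11ᵀ/m`:

```
T = Kᵀ (K Kᵀ + α H)⁺ ,   ŝ_l(t) = (T x(t))_l / sqrt([T K]_ll)
```

`α = 0` (pseudo-inverse) is the default in validation because the
standardized estimator then has exactly zero localization error for
noiseless point sources — verified for every source of the toy lead field.
For noisy use, `default_alpha` implements the usual heuristic
`trace(KKᵀ)/(m·SNR²)` with SNR = 3. Regional time courses are the
arithmetic mean of member-source standardized series; alternatives
(centroid source, first principal component) were rejected for sign
ambiguity. Regions are always ordered by ascending atlas code.

The packaged atlas lists the 90 standard AAL cerebrum regions plus four
cerebellar crus regions and one vermis region, giving the 95 nodes used
throughout; coarse lobe groupings follow the key-node reporting
convention.

## Connectivity

Phases come from the analytic signal of the band-limited regional series;
5 % of samples at each epoch edge are excluded (Hilbert edge effects).
PLV for a pair is `|mean over interior samples of exp(jΔφ)|`, averaged
across epochs (`concatenate=True` pools samples instead — the two differ,
and averaging is the default because epochs are the natural exchangeable
unit here). For N i.i.d. uniform phase differences the null mean is
`√π / (2√N)` ≈ 0.0886 at N = 100, which the implementation reproduces to
Monte-Carlo precision.

## Networks and metrics

* Proportional thresholding keeps the `round(s·n(n−1)/2)` largest
  off-diagonal weights, weights preserved. Ties break lexicographically on
  (row, col), which makes edge sets nested across densities and runs
  bit-reproducible across platforms.
* CC uses Onnela geometric-mean triangle intensities with the standard
  `k_i(k_i−1)` normalization; AC is Newman degree assortativity computed
  from edge end-degrees; path lengths are `1/weight`; GE counts
  disconnected pairs as zero efficiency; betweenness is unnormalized
  weighted betweenness with unordered pairs counted once. Degrees are
  binary edge counts. All five agree with exhaustive brute-force
  enumeration on every connected graph of ≤6 nodes.
* σ compares CC and CPL against degree-preserving Maslov–Sneppen
  surrogates with the original weight multiset shuffled onto the rewired
  edges. The default swap budget is 10× the edge count per surrogate
  (a fixed small swap count does not mix a ~500-edge graph), 100
  surrogates by default. A graph evaluated against its own randomization
  class gives σ ≈ 1; a ring-lattice/rewired small-world graph gives σ > 1.
* AUC is the trapezoid rule over the density grid with densities as
  fractions (so a constant metric v over 0.10–0.38 integrates to 0.28·v).
  Undefined levels (e.g. NaN assortativity on a degree-regular graph) are
  excluded with a warning.

**Monotonicity.** Adding edges cannot lengthen shortest paths, so GE and
degree sums are non-decreasing in density — asserted as invariants. The
group-mean CC curve is also non-decreasing on generator PLV networks
(individual-subject CC curves can dip slightly at high coupling).
Assortativity is *not* monotone: the focal clique's assortative structure
dilutes as weaker edges enter, so AC typically falls with density here.
Claims that GE decreases, or AC increases, with density describe other
datasets and are surfaced by the pipeline as documented-discrepancy
manifest flags rather than reproduced.

## Group statistics

Classical paired t-tests (two-tailed) on per-subject AUCs. Identical
samples return t = 0, p = 1; a constant nonzero difference raises (the t
statistic is genuinely undefined). The key-node screen runs one paired
test per region and by default reports raw p < 0.05 without
multiple-comparison correction — the conventional reporting style for this
design, recorded in every manifest — with Benjamini–Hochberg FDR as an
option. Under a null cohort the per-region detection rate matches the
nominal 5 % to Monte-Carlo precision (validated over 500 simulated
cohorts drawn at the nodal-AUC level, where the null is exact and the
study fits in seconds).

Validation of the planted contrast uses PLV computed directly from the
generator's ground-truth regional phases: the group_stats claims are
defined on generator output, and this route isolates the statistics from
source-imaging error. Through the full sensor → inverse → ROI route the
CC and GE contrasts survive unchanged, but spatial leakage of the toy
inverse (random lead field, no geometry) blurs the focal clique and can
reverse the sign of the smaller AC contrast. That is a property of the
toy forward model, not of the statistics; with realistic lead fields
leakage is what methods like orthogonalized connectivity address, which
is out of scope here.

## Questionnaire psychometrics

Cronbach's alpha uses sample variances; corrected item-total correlation
correlates an item with the sum of the others; alpha-if-deleted is alpha
recomputed on the reduced set (definitionally, to 1e-12). KMO uses
anti-image partial correlations from the inverse correlation matrix;
Bartlett's statistic is `−(n−1−(2p+5)/6)·ln det R`. Factor extraction is
principal components from the correlation matrix ("component matrix"
reporting convention indicates PCA rather than maximum-likelihood factor
analysis), rotated with varimax; factor signs are fixed so the dominant
loading is positive, and explained variance is reported from the
extraction eigenvalues (rotation redistributes variance and would make a
single-factor structure look bifactorial). Spearman p-values use the t
approximation, or the exact permutation distribution for n < 10; display
matrices blank cells with p above the masking threshold.

The default generator loading matrix groups the five environment items on
one factor and the four affective/seat items on the other, with
cross-loadings chosen so the overall-comfort item's implied correlations
rank static comfort ≈ 0.80 > valence ≈ 0.77 > arousal > aural pressure >
vibration > noise, and visual/thermal near zero. Responses are a linear
factor model scaled by 20 and clipped to the VAS range; with default
(standardizing) noise the population correlation matrix is exactly ΛΛᵀ
off the diagonal, so closed-form checks (Spearman–Brown: nine parallel
items at inter-item r = 0.5 give alpha = 0.9) hold in the large-sample
limit.

Rows are respondent-windows treated as independent samples. That ignores
within-subject correlation of repeated ratings; it matches the reporting
convention of such instruments but inflates effective sample size, which
is why no inferential claims are attached to the reliability estimates.

## Reproducibility and problem sizes

All randomness flows from a single master seed split per stage with
`numpy.random.SeedSequence`; identical config + seed reproduces every
output byte (tested). The validation studies use: 20 replicates of
20-subject cohorts for the planted contrast; 500 cohorts for type-I
control; 10⁴ pairs for the PLV null; 2×10⁴ rows for the asymptotic
psychometric checks; all connected ≤6-node graphs (141 with ≥1 edge in
the atlas enumeration) for metric verification. These sizes keep the full
validation under a few minutes on one CPU while leaving Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

* The toy lead field has no head geometry; localization results transfer
  to realistic forward models only qualitatively.
* PLV on mean ROI time courses inherits spatial-leakage bias; no leakage
  correction is implemented.
* The artifact rule is amplitude-only; real cabin EEG needs dedicated
  ocular/muscle handling.
* Gamma as defined (31–64 Hz) cannot be recovered from 0.01–40 Hz
  acquisitions; the module warns and proceeds.
* Sparsity range 10–38 % is a configuration constant, not derived from a
  range-determination procedure.
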