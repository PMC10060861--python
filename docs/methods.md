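# Methods

## The problem

Chronic pain is maintained not only by nociception but by cognitive and
affective processes — pain catastrophizing in particular. Resting-state fMRI
work links chronic pain to the default-mode (DMN) and dorsal-attention (DAN)
networks. This package implements a longitudinal analysis of that question:
does the *segregation* of canonical cortical networks, together with the
catastrophizing subdomains (rumination, magnification, helplessness), predict
how a person's pain experience changes over roughly a year — and does
helplessness *moderate* the brain–pain relationship?

Because participant-level data of such studies are typically not
redistributable, the package ships a synthetic-cohort generator with full
ground truth; every estimator is validated by parameter recovery and by
independent oracles rather than by re-fitting someone's raw data.

## System segregation

Let `z_ij = arctanh(r_ij)` be the Fisher-z transform of the Pearson
correlation between the nuisance-cleaned BOLD series of parcels *i* and *j*
(negative values truncated to zero; self-connections excluded). For a network
*net* in a node→network partition,

    W_net = mean z over unordered node pairs inside net
    B_net = mean z over (node in net, node outside net) pairs
    SyS_net = (W_net − B_net) / W_net

`SyS ≤ 1`, equals 1 when the network is isolated, 0 when within- and
between-network connectivity balance, and is undefined (flagged, never
silently 0) when `W_net = 0`. Pairs whose correlation was truncated to zero
stay in the denominators: truncation substitutes a value, it does not remove
a pair. `B_net` is the pooled mean over all net×non-net pairs, not a mean of
per-other-network means; with unequal network sizes the two differ and the
pooled form matches the "rest of the cortex" reading.

The default partition has 100 nodes in the seven canonical networks
(default, somatomotor, control, dorsoattention, salience/ventral-attention,
limbic, visual). The per-network node counts approximate the familiar
100-parcel scheme; no formula depends on them. Real atlases load from a
two-column TSV.

## Motion quality control

Framewise displacement per frame transition is the Power form

    FD_t = Σ|Δ translation_axis| + 50 mm · Σ|Δ rotation_axis|

with rotations in radians converted to arc length on a 50 mm sphere (the
constant of that formulation; configurable). A subject is excluded when at
least 50% of transitions exceed 0.5 mm ("at least" read as ≥). Motion files
use the MCFLIRT column order (3 rotations in radians, then 3 translations in
mm); a switch accepts translation-first dialects. When raw-length series are
supplied, a configurable number of leading dummy volumes (default 0, i.e.
already removed) is dropped before FD and connectivity.

## Nuisance model

Each parcel series is residualized on an intercept, the six realignment
parameters and their backward-difference derivatives (first row zero-padded),
a discrete-cosine drift basis containing the `K = floor(2·T·TR·cutoff)`
DCT-II components below 0.01 Hz, and any supplied tissue (WM/CSF) regressors.
Collinear confound columns are dropped by pivoted QR with a warning.
Correlations are clipped to ±(1 − 1e−7) before `arctanh` so perfect
correlations stay finite without reordering values.

## Instruments and the pain-experience outcome

* **BPI-SF**: intensity is the 0–10 mean over the last week; the seven
  interference items split into affective (relations, enjoyment, sleep, mood)
  and activity (walking, general activity, work) means, with sleep assigned
  to the affective subdimension (a config option moves it out). The total is
  the seven-item mean.
* **PCS**: 13 items on 0–4, total 0–52. Subscale keying follows the original
  instrument — helplessness items 1–5 and 12 (max 24), magnification 6, 7, 13
  (max 12), rumination 8–11 (max 16) — and is configurable, since only the
  subscale names and maxima are fixed by the protocol.
* **Pain experience** at a timepoint is the arithmetic mean of intensity and
  affective interference on their shared 0–10 scale; the longitudinal outcome
  is T2 − T1 (positive = worsening). The protocol's displayed formula shows a
  minus sign where its text says "mean"; the observed T1 composites only
  reproduce under the mean reading, which is therefore the default, with
  `variant="difference"` available for sensitivity analyses.
* **Group classification** from the two screening answers: yes-yes → pain,
  no-no → no pain; recovered (yes-no) and developed (no-yes) are labelled and
  excluded from the main contrast. No imputation anywhere: a missing item is
  an error.

## Inferential chain

Group contrasts use Welch t tests (raw data) and, for published-summary
recomputation, the pooled-variance one-way ANOVA F — for two groups the
square of the pooled t — because that is the form two-group F columns derived
from means/SDs reproduce. The sex contrast is a 2×2 Pearson chi-square
without continuity correction (cell counts rebuilt by rounding proportion ×
n); with Yates' correction the published value is not recoverable. Partial
correlations use the residual method with p from t on n − k − 2 df.
Regressions z-score all variables so coefficients are standardized betas;
VIF_j = 1/(1 − R²_j) with a configurable flag threshold of 10. Covariate-
adjusted group comparisons use the partial F of the group term. No
multiple-comparison correction is applied by default (matching the primary
analysis it mirrors); a Benjamini–Hochberg helper is provided.

### Moderation and Johnson–Neyman

`ModerationModel` fits `y ~ focal + moderator + focal×moderator + covariates`
by OLS with focal and moderator mean-centered before forming the product
(the common social-science convention; a flag disables it — centering moves
b1/b2 but not b3 or the boundaries). The interaction CI is a case-resampling
percentile bootstrap (default 5,000 resamples, 95%), seed-reproducible and
vectorized over resamples; rank-deficient resamples are redrawn and counted.
BCa is available as an option. The Johnson–Neyman boundaries solve

    (b1 + b3 w)² = t²_crit [Var(b1) + 2w Cov(b1,b3) + w² Var(b3)]

for the centered moderator w and are mapped back to the original scale;
roots outside the observed moderator range are reported as "none in range",
and each segment carries the significance and sign of the conditional
effect at its midpoint. A positive-*semi*definite coefficient covariance is
accepted (a known-zero interaction has zero variance and a constant
conditional effect); an indefinite one is an error.

## The synthetic cohort

The generator defines the study conditions; its defaults are fixed once.

* **Time series**: `n_volumes = 740` (750 acquired minus 10 dummy scans) at
  TR = 0.8 s; zero-mean Gaussian with block covariance — `r_within[net]`
  inside networks, `r_between` across, 1 on the diagonal. The analytic
  segregation of this model is `1 − arctanh(r_between)/arctanh(r_within)`.
  Defaults `r_between = 0.20` and per-network `r_within` between 0.26 and
  0.33 were chosen so the analytic SyS matches typical observed per-network
  means (≈0.25–0.42). Between-subject SyS variance comes from jittering the
  within-network Fisher-z level with SD 0.10 (giving an SyS SD comparable to
  observed cohorts); a non-positive-definite correlation combination is
  rejected at config time.
* **Motion**: AR(1) positions (coefficient 0.95) on all six rigid-body
  parameters, rotations scaled by 1/50 so both contribute comparably to FD;
  the trace is rescaled so each subject's realized mean FD equals a target
  drawn per group (no-pain 0.163 mm, pain 0.179 mm, between-subject SD
  0.05 mm — the source table's printed FD SDs are typographically impossible,
  so 0.05 is this package's choice). No generative motion model was specified
  anywhere; only the FD consequences matter downstream.
* **Phenotypes**: group membership by prevalence 133/347; demographics and
  health questionnaires at group-conditional levels. For the pain group, the
  change in pain experience is planted as

      ΔPE = Σ β_j z_j + β_int z_help z_DMN + ε,  ε ~ N(0, noise_sd²)

  with predictors z-scored within the pain group and default standardized
  effects helplessness 0.325, DMN SyS 0.193, DAN SyS −0.215, baseline
  intensity −0.428, affective interference −0.678, activity interference
  0.255 and interaction 0.25 (no published standardized interaction size
  exists; 0.25 is a moderate planted default). The planted coefficients apply
  to z-scored predictors while the outcome stays on its natural 0–10 scale,
  which is how the recovery checks phrase truth (e.g. "plant b3 = 0.4").
  Item-level responses are then generated *consistently with* the target
  composites — continuous BPI items uniformly on the constrained simplex with
  the exact target sum, integer PCS items uniformly subject to the subscale
  sum — so the scoring layer is exercised, and with zero noise the planted
  model is recoverable to machine precision. Composites are clipped to
  instrument bounds; the clip rate is recorded in the ground truth (≈7%
  under defaults, mostly floor effects on interference) and a rate above 20%
  warns that planted effects will be attenuated.

What the generator does **not** emulate: hemodynamic autocorrelation and
spectra (samples are temporally white), spatially heterogeneous edge
strengths within a network, distance-dependent motion artifacts, item-level
response styles, missing data, or selection effects. Passing recovery tests
therefore validate the estimators and the inferential chain, not the
biological claims of any particular cohort.

## Validation sizes and numerical choices

The recovery suite runs, at defaults: 50 simulated subjects (100 nodes, 740
volumes, `r_within = 0.5`, `r_between = 0.1`, subject jitter 0 since the
correlations are fixed by the check) for analytic SyS recovery — observed
per-network error < 0.005 against the analytic 0.8173, asserted at 0.02; 100
random 10-node instances for segregation-vs-pair-loop equivalence (< 1e−10);
100 instances of the partial-correlation precision-matrix identity
(< 1e−10); 50 random moderation fits for Johnson–Neyman-vs-grid agreement
(within one step of a 20,001-point grid); 100 replicates (n = 300, noise SD
1, 5,000 resamples) for bootstrap coverage of a planted interaction 0.4, and
200 null replicates for type-I calibration of the same test. Seeds propagate
through `numpy.random.SeedSequence` spawning, so every artifact is
bit-reproducible for a fixed config and independent across subjects.

Degenerate inputs are errors, not silent values: zero-variance node series
name the node; both-samples-zero-variance t tests, zero pooled variance,
rank-deficient regression designs, and infeasible item splits all raise;
fewer than three pain-group subjects cannot support the planted z-scored
model and raise at generation time.

## Known limitations

* The generator plants effects with the reduced-model coefficients as if
  they came from the reduced model; the source analysis reported them from a
  model with more covariates. Recovery checks target the generator's own
  truth, not any published coefficient.
* Estimated SyS at finite scan length attenuates regressions that planted
  effects on true SyS; at 740 volumes the estimation SD (≈0.01) is small
  against the between-subject SD (≈0.09), so the attenuation is negligible,
  but it is visible in short-scan configurations.
* Voxel-level preprocessing (realignment, normalization, tissue
  segmentation) is out of scope; the pipeline starts at parcel space and at
  realignment-parameter traces.
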