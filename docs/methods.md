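# Methods

## Measurement model

A membrane carries 55 analytes as duplicate circular spots, six positive
reference spots, and a clear background region. Densitometry reads the
arithmetic mean pixel intensity of each spot ROI (a fixed-radius disk;
membership by pixel-centre-in-disk, which is deterministic and checkable
against brute-force pixel enumeration), averages the two replicates,
subtracts the mean of the background rectangle, and divides by the
background-subtracted mean of the six reference-spot means:

```
level = max(0, dup_mean − bg_mean) / (ref_mean − bg_mean)
```

Whether the reference average should itself be background-subtracted is
not dictated by the assay; we subtract by default
(`subtract_reference_background=True`) because it is the choice that
makes the ratio exactly invariant under a global intensity rescaling of
the scan — a property the suite verifies to 1e−10 relative on noiseless
renders. Negative net signals are clamped to 0 and marked
non-detectable: the scale is semi-quantitative and non-negative, and ND
is a category, not a measurement of zero.

**Detection rule.** No numeric detection limit comes with the assay, so
a signal-above-blank criterion is used: detectable iff
`dup_mean − bg_mean > k × bg_pixel_sd`, default `k = 3` (configurable).
On noiseless synthetic membranes `bg_sd = 0`, so any positive net signal
is detectable — which is what makes exact end-to-end recovery testable.

**Saturation.** Pixels are capped at 110 arbitrary units. A spot is
flagged saturated when ≥ 50% of its ROI pixels sit at the cap (tolerant
of clipped noise spikes). Saturated levels are retained but flagged;
they are non-quantitative by construction.

**Inversion.** Scanned films are usually inverted before densitometry;
`invert_image` is the involution `pixel → cap − pixel`. Synthetic images
are rendered pre-inverted (signal bright), so the toggle defaults off.

## Exposure merging, imputation, accounting

Each sample is read at a short (3 min) and a long (30 min) exposure.
Per patient–protein: if the short exposure is detectable at BL, SOM and
EOT, the short-exposure levels are used at all three time points;
otherwise the long-exposure levels are used. The rule is deliberately
per patient–protein so that within-patient changes never mix gain
scales. Detectability of the merged values is taken from the exposure
actually used.

Below-detection entries of a protein are imputed to 50% of the lowest
*detected* level of that protein over all patients and time points
(detected values only — letting imputed values feed back into the
minimum would make the rule circular; this also makes imputation
idempotent, and every imputed value strictly smaller than every detected
one). Proteins detected in no sample are excluded from all statistical
outputs and reported only in the detectability table and the exclusion
list.

Detectability percentages are `100 × detected/total`, rounded to the
nearest integer half-away-from-zero (2 of 22 → 9), with 0% rendered as
`ND`. The same counting operations accept an externally supplied printed
grid; the bundled `reference_detectability.tsv` (the per-protein grid
observed in the original 22-patient serum study this pipeline
re-implements) yields 8 all-ND proteins and fully-detected proportions
of 24/25/18% at BL/SOM/EOT. (The source publication quotes 22% at BL;
its own printed grid gives 13/55 = 24%, and the package reports what it
computes.)

## Statistics

**Dynamics.** For each protein and phase (BL→SOM, SOM→EOT), differences
`d_i = log(later) − log(earlier)` are computed on imputed levels
(natural log; the base affects neither ranks nor signs). Pairs with
`d_i = 0` drop from the test. Both-ND pairs are equal after half-minimum
imputation, hence zero, hence dropped — and are tallied as the ND count;
this single rule reproduces the up/ND/down accounting without a second
exclusion rule. A pair ND on one side only enters as a real change (the
imputed value is a usable number, which is the entire point of imputing
instead of nulling). The two-sided Wilcoxon signed-rank p uses the exact
null distribution for up to 25 effective pairs, computed by convolution
over doubled midranks (so ties are handled exactly); beyond 25 the
tie-corrected normal approximation (no continuity correction) is used.
A 22-patient cohort therefore always takes the exact path. Direction is
the sign of the median non-zero difference.

**Associations.** Spearman rank correlation with midranks (imputed
values tie at the common imputed level): BL level vs TTP1, SOM level vs
TTP2, and the landmark analysis of the BL→SOM relative change
(operationalized as the ratio SOM/BL, rank-identical to the log
difference) vs TTP2. The two-sided p is exact by full permutation
enumeration for n ≤ 10, t-approximated above. Zero rank variance yields
a flagged, undefined result rather than a number.

**Reporting.** Results are ranked by ascending nominal p (ties broken by
protein name); p < 0.005 is labelled `stronger`, 0.005 ≤ p < 0.05
`weak`, otherwise `none`. No multiple-testing adjustment is applied —
the tests rank proteins by evidence — and every statistical output file
carries that caveat.

## Synthetic cohorts and membranes

The generator defines the study conditions: 22 patients × 3 time points
× 2 exposures (132 membranes per cohort).

* **Abundance tiers.** Patient baselines are log-normal with
  between-patient SD `sigma_between = 1.0` (log scale). Each protein's
  median is pitched so that the expected fraction of patients above the
  long-exposure detection limit matches the bundled reference grid —
  the panel therefore spans truly absent proteins (level 0 everywhere;
  8 of 55), rarely detectable, and always-detectable tiers, and the
  brightest tier saturates the long exposure in a minority of patients.
* **Dynamics.** Per-sample biological/assay noise is multiplicative
  log-normal with `sigma_within = 0.3`. Programmed effects multiply
  levels between adjacent time points (default plan: 2-fold-scale
  decreases of eight proteins and increases of four during induction;
  increases of five and one decrease during maintenance, in 80% of
  patients), chosen to mirror the dynamic patterns the assay was built
  to detect.
* **Outcomes.** TTP2 is log-normal (median 119 days, log-SD 0.5,
  floor 30); TTP1 = TTP2 + a uniform induction length of 118–163 days,
  so TTP1 > TTP2 always. Planned TTP2 concordance is induced by a
  Gaussian-copula rank interleaving: the normal scores of each planned
  protein's BL→SOM log-change are combined with weights
  `c = 2 sin(π·ρ/6)` (the classical Pearson↔Spearman relation) plus
  independent noise, and the sorted TTP2 values are assigned by the rank
  of that latent score. This controls the Spearman target
  distribution-free of the TTP marginal; a 0.5 target is recovered to
  within ±0.1 in mean over replicate cohorts.
* **Rendering.** Spot intensity `min(cap, gain·level + bg)` on a flat
  background `bg = 5`, gains 1 (3 min) and 10 (30 min) — proportional to
  exposure time — additive Gaussian pixel noise (`sd = 1`), clipped to
  `[0, 110]`. Reference spots carry a fixed concentration of 8, kept
  sub-saturated at both exposures (10·8+5 < 110), mirroring the choice
  of exposures short enough to keep the reference spots quantifiable.
  With these defaults the low tier is below detection at the short
  exposure (limit ≈ 3 concentration units) but quantifiable at the long
  one (limit ≈ 0.3), which is exactly the situation the
  exposure-selection rule exists for. Images quantize to 16-bit on disk
  (worst-case error cap/65535 ≈ 0.002 intensity units); exactness tests
  run on the in-memory path.

What the generator does **not** emulate: spatial background gradients,
spot morphology defects, film grain or optical blur, inter-membrane
batch effects, hemolysis artefacts, and any real vendor geometry (the
grid template is a functional stand-in). Passing tests therefore
validate the *procedure* — densitometry arithmetic, merging, imputation
and inference — not robustness to those real-world artefacts.

## Numerical choices and degenerate inputs

* Exact signed-rank: midranks are doubled to integers and the null mass
  function built by convolution; `p = min(1, 2·min(P(W⁺≤w), P(W⁺≥w)))`.
  `n_effective = 0` returns p = 1, direction `none`.
* Exact Spearman permutation p compares |rank covariance| with a 1e−9
  slack (rank covariances are half-integers, so this only absorbs float
  error).
* A membrane whose reference mean does not exceed background is rejected
  (quality-control error) rather than producing unstable ratios.
* Detectability grids with mixed `ND`/integer cells are accepted
  anywhere percentages are counted.
* Simulation-study calibration is reported over tests able to reject:
  with α = 0.05 the exact discrete test cannot produce p < 0.05 for
  n_effective ≤ 5 (minimum attainable p is 2/2^n), so protein×replicate
  tests below that size — mostly-ND proteins — are excluded from the
  rejection-rate denominator. Including them would measure the panel's
  detectability mix, not the test's calibration. The conditional rate on
  null cohorts sits near 0.045; the unconditional rate is lower, as
  expected for a panel where roughly a third of proteins are detected in
  few patients.

## Problem sizes

Monte-Carlo summaries use 22-patient cohorts throughout: 1000 replicates
for null calibration in the test suite (300 in the acceptance script),
500 (200) for power and landmark-concordance recovery, 200 cohorts for
generator-level checks. Image-level exactness checks render full
132-membrane cohorts noiselessly.

## Known limitations

* The default membrane geometry, gains and noise levels are chosen for
  testability and realistic tier structure, not fitted to any vendor's
  chemistry.
* The exposure-selection rule assumes both exposures exist for every
  sample; partial acquisitions are an error, not a fallback.
* Survival methods with censoring are out of scope by design: the
  intended cohorts include only patients who progressed, so TTP is a
  complete observation and rank correlation is the appropriate tool.
* No multiplicity adjustment is offered; the output is an evidence
  ranking, and the report says so on every file.
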