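# Methods

## Measurement model

A bread-loaf slice is represented by a single-plane grayscale image in
arbitrary device units (a.u.) with a physical pixel size (default 85 µm, the
resolution of the back-table imaging system; frames are nominally
1300 × 964 pixels) and a set of labeled polygons in pixel coordinates:
tumor, tissue (the loaf outline), optional stasis regions, and an optional
operator-chosen representative background area. Intensities are read
bit-exactly; no rescaling, exposure or flat-field correction is applied —
the device auto-exposes and exports post-processed arbitrary units, so any
correction would be invented.

Polygons are rasterized by pixel-center sampling: a pixel (row, col) belongs
to a region iff its center (col + 0.5, row + 0.5) lies strictly inside the
polygon union (origin top-left, y down). This makes axis-aligned examples
exact and is checked against an independent per-point point-in-polygon
oracle in the tests.

Distance to tumor is the Euclidean distance between pixel centers, with the
tumor treated as its rasterized pixel set rather than its polygon outline;
sub-pixel distance to an outline is not well defined on the raster and the
pixel-set convention is exactly checkable against an all-pairs brute-force
oracle. The distance field is computed with an exact Euclidean distance
transform. Bands partition the tissue:

- rim: non-tumor tissue with d ≤ 3 mm (threshold inclusive, "up to");
- background: tissue with d ≥ 5 mm (inclusive, "from");
- gap: the remaining 3 mm < d < 5 mm shell, deliberately an explicit class
  so that the discarded pixels are auditable. When the two thresholds
  coincide the rim takes the boundary pixels and the gap is empty.

MSFI and MBFI are arithmetic means over rim and background pixels, SBR
their ratio, and the maximum intensity is taken over a configurable scope —
default all tissue pixels of the analyzed loaf, because a whole-frame
maximum can be captured by calibration artifacts at the frame edge;
whole-image and rim-only scopes are available.

Three rules follow the clinical workflow:

- **Central loaf**: the loaf with the largest rasterized tumor
  cross-section is analyzed (the maximal section is the standard surrogate
  for the lesion's center; ties break to the lowest index).
- **Stasis recalculation**: if a representative background area was drawn,
  MBFI is recomputed over it (intersected with tissue at background
  distance); otherwise, if stasis polygons exist, stasis pixels are
  subtracted from the background. The result is flagged.
- **100 mm² sufficiency**: the rule is applied to the background region
  (d ≥ 5 mm), the tissue actually used for MBFI. A smaller background is
  augmented by appending other loaves' own ≥ 5 mm regions in manifest order
  (deterministic, logged) until the cumulative area reaches 100 mm², with
  MBFI recomputed as the pooled pixel mean; if the total still falls short
  the lesion is flagged excluded and MBFI/SBR are withheld.

## Clinical classifiers

Response is classified per lesion from radiological longest diameters:
disappearance → complete response; change ≤ −30% → partial response;
change ≥ +20% → progressive disease; otherwise stable disease. Boundary
ties go to PR/PD (the "at least" wording); the RECIST 1.1 absolute 5 mm
growth minimum is not applied because the cohort rule is purely
percentage-based. Steatosis uses the Brunt bins none < 5%, mild 5–33%,
moderate 34–66%, severe > 66%; the unassigned 33–34% sliver is mapped to
mild so the scheme is contiguous and every fraction has exactly one grade.
Pretreatment means the last chemotherapy cycle started within three months
before surgery, operationalized as 90 days (no day count is standard;
calendar-month arithmetic is ambiguous).

## Statistical layer

Test choice per parameter is configured, defaulting to how each parameter
is distributed in practice: maximum intensity, diameter, age and BMI are
compared with a one-way two-group ANOVA (identical to the pooled two-sample
t-test, F = t²; a summary-statistics form allows validation directly
against published mean ± SD tables), while MSFI, MBFI and SBR — strongly
right-skewed — use a two-sided Mann–Whitney U test. The Mann–Whitney p is
exact by full labeling enumeration when n₁ + n₂ ≤ 12 without ties, else a
normal approximation with tie and continuity correction. Pearson chi-square
is used without continuity correction; Kruskal–Wallis (tie-corrected,
χ² approximation) relates steatosis grade to MBFI; Spearman correlation
(t approximation, n − 2 df) relates tumor size to each parameter. Each
fluorescence parameter is regressed by OLS with intercept on pretreatment
(0/1), superficiality (0/1) and tumor size (cm); per-coefficient two-sided
t tests use n − 4 df. Quantiles are linear-interpolation; p-values are
displayed half-up to 3 decimals with "< 0.001" below; no multiple-testing
correction is applied and 0.05 is the significance threshold. The response
stratification is reported descriptively only — subgroups are too small to
test. Constant-input or single-group strata are skipped with a log entry,
never silently.

## Synthetic data

The phantom paints tumor-core level inside the tumor ellipse and
b + a·exp(−d/λ) outside (background level b, rim amplitude a, decay length
λ), plus optional stasis blobs, plus additive Gaussian noise truncated at
zero. The exponential profile is a modeling choice — the true in-patient
rim profile is unknown beyond the rim being a few mm wide — selected
because it yields an analytic band average on the same grid, so a
noise-free phantom's measured MSFI must equal the ground-truth mean to
floating-point precision (≤ 1e-9 relative, asserted). Defaults:
b = 0.104 a.u. (the cohort's median background), tumor core 0.05 a.u.,
a = 1.0 a.u., λ = 1 mm, noise SD 0.02 a.u., tumor semi-axes 4 × 3 mm in a
20 × 15 mm tissue ellipse. Multi-loaf specimens scale the tumor
cross-section like an ellipsoid's circles so the designated central loaf is
the argmax, and can force one loaf's tissue small enough to trip the
100 mm² rule.

The cohort generator draws covariates at the study's marginals
(chemotherapy prevalence 10/32, capsular 22/32, diameters normal
29.9 ± 15.4 mm truncated at 5 mm by resampling, steatosis grades
9:19:4:0/32, sex 19:13, age 63.2 ± 8.9, BMI 25.3 ± 3.0) and builds each
fluorescence outcome as a log-normal baseline (capturing the skew implied
by median [IQR] reporting; untreated medians MSFI 0.65, MBFI 0.104,
SBR 6.08, maximum 1.80 a.u., with log-scale sigmas 0.65/0.55/0.55/0.25
matched roughly to the reported IQRs) plus planted linear effects plus
Gaussian residual (SD 0.10/0.02/1.0/0.35). The planted effects are the
regression-scale associations: chemotherapy −0.36 on MSFI, −3.8 on SBR,
−0.72 on maximum intensity; +0.25 maximum intensity per cm of diameter.
Superficiality is planted null. SBR is drawn as its own outcome rather
than as a ratio, so its planted coefficient is exactly recoverable by OLS.
Outcomes are not clipped at zero — a pretreated draw can go slightly
negative — because clipping would bias the linear-effect recovery the
generator exists to validate.

What the phantoms deliberately do not model: photon transport and depth
attenuation, white-light/NIR misregistration, annotation error, spatial
noise correlation, and multiple lesions per patient. Passing tests
therefore validate the measurement and statistics chain, not the physics of
any particular device.

## Validation strategy and problem sizes

Every non-trivial computation is checked against an independent oracle:
rasterization against per-point point-in-polygon; the distance field and
band masks against all-pairs brute force (200 random 64 × 64 instances in
the acceptance suite); the exact Mann–Whitney against full permutation
enumeration for all splits with n₁ + n₂ ≤ 10; 2 × 2 chi-square against the
closed form N(ad − bc)²/(r₁r₂c₁c₂); OLS against the normal equations; and
three published cohort-table comparisons recomputed from their summary
statistics (diameter p = 0.073, age p = 0.516, sex-ratio χ² = 5.203,
p = 0.0225 — the Pearson statistic; the likelihood-ratio variant gives
0.022, and which variant the original software reported is unknowable from
the table alone, so Pearson is retained as the named default).

Regression recovery is scored as 2-SE coverage of the planted coefficients
on n = 200 cohorts. True coverage is ≈ 95%; the check requires ≥ 93% and is
evaluated over 400 seeded replicates (about a second of compute) so that
the binomial Monte-Carlo error of the coverage estimate (~1 point) is small
against the 2-point margin; at 100 replicates the estimate's ±2-point noise
would dominate the margin. Phantom checks use 300 × 300 grids
(25.5 × 25.5 mm at 85 µm), large enough for a ≥ 5 mm background ring of a
few hundred mm² around a 6 × 5 mm tumor while keeping the whole suite in
seconds.

## Known limitations

- The rim profile, noise model and cohort outcome scales are plausible
  stand-ins, not fits to released data; the generator's manifests label
  them as placeholders.
- Distance is 2-D within a loaf; no 3-D reconstruction across loaves.
- One lesion per patient; no mixed-effects structure.
- The pipeline assumes white-light and NIR frames are co-registered as
  produced by the imaging system.
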