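# Methods

## The chronology model

Amelogenesis is treated as a two-stage clock. Ameloblasts are recruited along
the enamel–dentine junction (EDJ) from the dentine horn towards the cervix;
once recruited, each cell secretes enamel matrix outward at the local daily
secretion rate (DSR). Daily cross-striations make the DSR directly measurable
(`run length / number of striations`, µm/day), and striae of Retzius are
isochrones: a stria through the outer end of a prism segment meets the EDJ at
the point being recruited at that same moment.

The segment-chaining reconstruction uses exactly this property. Starting at
the dentine horn (or the most cuspal intact prism when the horn is worn), a
nominal 200 µm prism segment is traced; its terminal stria is followed to the
EDJ; the next segment starts there. Each segment contributes
`days = length / local DSR`, where the local DSR is the **unweighted mean of
the per-run readings** for that segment (each run is one local reading; an
alternative pooled-lengths/pooled-counts estimator differs only at the third
decimal on realistic runs, and the unweighted mean is the more conservative
reading of "measured and divided per run"). Cumulative days give the crown
formation time (CFT). The neonatal line (NNL) is dated by intersecting it
with the chained prisms — linearly interpolated in prism arc length within
the crossed segment, a sub-segment rule the source procedure leaves
unspecified — and splits CFT into crown initiation (Ci, days before birth)
and crown completion (Cc = CFT − Ci, days after birth). Accentuated lines are
dated the same way and reported relative to birth.

Exclusion semantics mirror standard practice: a worn dentine horn makes CFT
and Ci minimum estimates (flagged, excluded from group means) but leaves Cc
intact, because Cc is anchored at the NNL; a broken cervix invalidates CFT
and Cc but not Ci. Day values round half-away-from-zero to integers for
reporting; floats are kept internally.

Numerical choices: chaining tolerance 25 µm (digitizing jitter at 10×
magnification; configurable), gaps beyond it are hard errors naming the
segment; a stria that stops short of the EDJ is accepted if its endpoint
projects within the same tolerance; with multiple prism crossings the one
nearest the EDJ is used and flagged. Local DSRs outside 1–8 µm/day raise a
QC flag, not an error. Runs shorter than 6 striations load with a warning.

## Extension rates and smoothing

Each chained segment covers an EDJ arc interval in known days, so the local
enamel extension rate is `EER = arc span / days`. The trend over the
(birth-centred) timeline is a **natural cubic smoothing spline** in the
Green–Silverman construction — the 1-D analogue of a thin-plate spline —
with the penalty tuned by bisection to each candidate effective df in a grid
(default 3…12) and the winner picked by GCV, `n·RSS/(n − edf)²`. The penalty
annihilates affine functions, so straight-line data are reproduced exactly at
any df. Duplicated x-values are merged with proportional weights; exact
replication of a data set therefore leaves the fitted curve unchanged at
matched df (the penalty rescales by the replication factor), but the
GCV-chosen df itself may grow, since replication doubles the apparent sample
— a documented property of GCV, not a defect. The choice of GCV (rather than
AIC) and the df grid are package defaults; the source procedure states only
"df minimizing error and residual deviance".

## Robust regression

Cumulative secretion days are regressed on cumulative prism length with the
intercept forced to zero (no length ⇒ no days). The fit is an M-estimate by
IRLS with Tukey bisquare weights (c = 4.685, 95% Gaussian efficiency) and a
normalized-MAD residual scale recomputed each iteration; convergence at
relative slope change < 1e-8 or 50 iterations; a Huber variant (c = 1.345) is
provided. When the IRLS collapses onto an exact fit of a majority of points
(MAD ≈ 0), weights are reported as the exact-fit indicator. The reported
uncentered adjusted R², `1 − (RSS/(n−1))/(Σy²/n)`, is flagged
*indicative-only*: through-origin R² is not comparable to the centred kind.
The response/predictor orientation (days on length) is chosen so the slope is
in days/µm, the reciprocal of a length-weighted mean DSR — for pairs
`(d·r, d)` with rate `r ~ N(µ, σ)` independent of duration `d`, the
through-origin slope converges to `E r / E r²`, ≈ 0.313 days/µm at
µ = 3.17, σ = 0.26.

## DSR surfaces

Scattered DSR samples (~400 per tooth) are smoothed with a full-rank 2-D
thin-plate spline: one `r² log r` basis centre per sample plus an unpenalized
affine part, ridge penalty λ on the radial coefficients selected by GCV over
13 log-spaced values in 1e-4…1e2 (coordinates are pre-scaled by the
bounding-box diagonal so the grid is geometry-independent). λ→0 interpolates;
planes are reproduced exactly at any λ. Evaluation grids (default 20 µm) are
masked to the closed enamel outline by the even-odd rule with on-boundary
points counted inside.

## Group statistics

The two-group battery gates on Shapiro–Wilk normality of each group
(delegated to scipy's Royston implementation) at α = 0.05: both normal → a
two-sided variance-ratio F-test chooses pooled-variance vs Welch t;
otherwise Mann–Whitney U. The full gate trace is recorded in every result.
The Mann–Whitney statistic uses midranks (so `U_a + U_b = n_a·n_b` holds with
ties); its p-value uses the exact null distribution (standard counting
recurrence) for tie-free samples with `n_a·n_b ≤ 400`, else the normal
approximation with tie correction and continuity correction. Note a
limitation inherited from small samples: with a 9-vs-3 split, a genuinely
large variance ratio (F ≈ 15) is still not significant under the two-sided
F-test, so the gate stays with the pooled t; reports that quote fractional
Welch df for such splits have effectively skipped the gate. Cohen's d is the
pooled-sd version. Sex calls are a presence/absence rule on the two
amelogenin marker peptides (AMELY ⇒ male; AMELX alone ⇒ female; neither ⇒
indeterminate), applied per individual, with the marker m/z values carried as
metadata.

## The simulator

The generator is the package's ground-truth channel; its defaults are the
study conditions, not tuning knobs.

- **Geometry**: the EDJ is a circular arc (radius 2500 µm) from horn to
  cervix in a 2-D section plane; prisms run radially (straight, never
  crossing). All pipeline mathematics uses arc lengths only, so the simple
  shape loses no generality.
- **Recruitment**: EER(t) = floor + (initial − floor)·exp(−t/τ), default
  12 → 3.5 µm/day with τ = 120 d — fast cuspal recruitment decaying to a
  cervical floor. Crown formation ends when the integrated front A(t) reaches
  the cervix; the default EDJ length (≈ 2330 µm) is derived so this happens
  at exactly CFT = 386 d. A mismatched (length, CFT) pair is an error
  reporting the implied duration.
- **Secretion field**: inner 200 µm at a depth-constant rate — a smooth
  three-cosine field along the EDJ (relative sd 7.5% around the 3.17 µm/day
  mean, keeping run readings inside the plausible 2.3–4.3 µm/day band) times
  a prenatal/postnatal step at birth (ratio 0.975, normalized so time-uniform
  run sampling averages 3.17; prenatal ≈ 3.20, postnatal ≈ 3.13). Beyond
  200 µm the rate ramps up linearly (+0.8 per 1000 µm), giving the familiar
  slow-inner/fast-outer topography. Each ameloblast secretes for 250 d or
  until crown completion, whichever is sooner.
- **Markings**: striae are exact isochrones of this field; one is emitted at
  every chain-boundary time (so chaining is exact before noise), plus the NNL
  at the birth day, accentuated lines at the configured stress days (defaults
  −40 and +120 d around birth), and background striae every 8 d — a
  literature-typical near-weekly periodicity, assumed because the sample's
  own periodicity is not reported.
- **Measurement**: 8 cross-striation runs per segment at evenly spaced
  depths (the study's ≈1855 inner-enamel readings over 34 teeth ≈ 8 per
  chained segment), each 6–12 striations, with multiplicative
  Normal(1, 0.03) length noise. Cuspal wear removes the first prisms and
  sets the worn-horn flag.
- **Cohorts** jitter CFT/Ci/mean-DSR between teeth (sd 27/19/0.05, the
  between-tooth spreads of the bundled table); arch-specific CFT means
  (353/403 d) are available for end-to-end power checks.

What the simulator does **not** emulate: prism decussation and curvature,
Retzius-periodicity variation, enamel thickness profiles beyond the secretion
span rule, diagenesis, wear geometry beyond truncation, or tracing-coordinate
jitter (noise enters through run lengths; the chaining-tolerance machinery is
exercised by explicit perturbation in tests). Passing recovery tests
therefore demonstrate correctness of the reconstruction arithmetic and its
noise propagation, not robustness to every failure mode of real micrographs.

## Problem sizes and defaults used in checks

Recovery checks use 20-tooth cohorts at the defaults above (≈ 7 segments and
2 stress lines per tooth); surface checks use 400 noisy samples with 400
held-out noiseless sites; regression checks use 500 pairs; calibration of the
gated battery uses 2000 replicates of 20-vs-20 samples for a normal and a
log-normal (heavy-tailed) regime. These sizes make the whole battery run in
about a minute on one CPU while keeping Monte-Carlo error well below the
asserted tolerances.

## Known limitations

- The sub-segment placement of birth/stress days is linear interpolation; if
  DSR drifts strongly within a segment the true placement is slightly convex.
- The bundled table's upper-arch Cc mean computes to 178.8 → 179 d; published
  summaries quoting 178 d presumably rounded differently.
- Group means for CFT/Ci depend on the worn-horn eligibility flags as given;
  the package does not infer wear from geometry.
- The exact Mann–Whitney null is used only for tie-free small samples; tied
  small samples fall back to the tie-corrected normal approximation.
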