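# Methods

## Monitored statistic

For one case, a *reference* plan (computed by an automated planning
service on a standardized beam model) and a *local* recalculation of the
same plan are each reduced to per-structure mean doses. The monitored
quantity is, per structure *s*,

    d(s) = 100 · (D̄_local(s) − D̄_ref(s)) / D̄_ref(s)   [%]

relative to the reference plan. Mean dose was chosen as the monitored
metric because it is robust to the systematic surface-region discrepancies
that different TPSs are expected to show; the aim is detection of gross
process changes, not plan quality scoring. Maximum dose, hot-volume doses
and other DVH metrics are out of scope.

Structures whose reference mean dose is at or below `dose_floor`
(default 0.01 Gy) are skipped: the ratio is numerically meaningless near a
zero denominator. The floor is configurable and only matters for
structures essentially outside the treated volume.

## Mean dose from a grid and contours

Dose grids are axis-aligned, uniformly spaced, with values at voxel
centers (the DICOM `ImagePositionPatient` convention); oblique
orientations are rejected rather than supported half-way. Structures are
closed planar polygons on constant-z planes.

A voxel belongs to a structure iff its center lies within half the slice
pitch of a contour plane and inside that plane's polygon(s) under the
even-odd rule; multiple polygons on one plane XOR together, which gives
holes and ring structures for free. No partial-volume weighting is
applied: the mean is the unweighted average over included voxel centers.
This keeps the operation exactly checkable against a brute-force
point-in-polygon loop, which the test suite does on random star-shaped
polygons.

When the two plans live on different grids, the *reference* grid is
authoritative: the local grid is resampled onto it by trilinear
interpolation before masking, so each structure has a single voxel mask
per case and differences are attributable to dose, not geometry. Resampled
points outside the source support carry NaN and are excluded from means;
this is the one place a dose array may be non-finite (readers reject
non-finite input).

## Control charts

Each structure's ordered series of d(s) values across cases is monitored
with an individuals chart:

    UCL = μ + 3σ        LCL = μ − 3σ

Estimation excludes out-of-limit observations: pass 0 computes μ, σ over
the full series; each later pass recomputes them over the observations
inside the previous pass's limits; iteration stops when the retained set
is stable (or after `max_iter`, default 10). Iterating to a fixed point
makes the rule idempotent — re-estimating on the retained subset changes
nothing — and allows a point excluded by an early, outlier-inflated σ to
re-enter once the limits settle. Single-pass behaviour is available by setting
`max_iter=1` (and no exclusion at all by `max_iter=0`); the number of
passes actually performed is recorded on the chart.

Two σ estimators:

* `sd` (default): sample standard deviation, n−1 denominator;
* `moving-range`: mean |successive difference| / 1.128, the conventional
  individuals-chart estimate (d₂ for subgroups of 2). It is offered
  because it is less inflated by a sustained shift inside the series.

Numerical conventions: a zero-variance retained set collapses both limits
onto μ with a warning rather than erroring; an observation exactly equal
to a limit is in-control (flagging is strict inequality); a chart needs
`min_points` (default 20) observations, also after exclusion, or it is
reported unchartable. On in-control Gaussian data the iterated rule
excludes slightly more than the nominal 3σ two-tail mass — the fixed point
of the truncation shrinks σ by ≈ 1.5 %, giving an expected outside
fraction near 0.0031 rather than 0.0027 — which the coverage test
tolerances reflect.

## Parameter sensitivity

A sweep recalculates a cohort at several values of one machine parameter —
dosimetric leaf gap (DLG, cm) or MLC transmission factor (MLC-TF) — with
the other held fixed. Default levels are DLG (0.1, 0.155, 0.17, 0.19,
0.23) cm and MLC-TF (0.0118, 0.0145, 0.0158, 0.0165), spanning the range
reported across clinics for these parameters, with the reference machine
at DLG 0.2 cm / MLC-TF 0.02. Levels are exact nominal values; a sweep in
which the held parameter varies is rejected as confounded. Both sweep
layouts are supported and must be declared: `crossed` (the same plans
recalculated at every level, the default) and `split` (distinct plans per
level).

Per structure, a chart is established at every level from that level's
cohort, and each chart statistic (UCL, mean, LCL) is regressed against
the parameter by OLS — one point per level, because the statistics exist
only per level. (A pooled per-case fit of the mean line is statistically
equivalent for balanced sweeps but gives misleading r² values; it was
considered and dropped.) Reported per structure:

* `rate_per_step`: mean-line slope × 0.1 cm (DLG) or × 0.01 (MLC-TF);
* `zero_crossing` = −intercept/slope of the mean line, the parameter value
  where local matches reference; an exactly zero slope flags the crossing
  undefined rather than returning ±∞.

Zero crossings are summarized over structures as mean ± sample SD, with
and without outliers. Small structures (eye, lens, optic nerve) respond
weakly and noisily to leaf-end modelling and can produce physically
impossible crossings that dominate the summary. Because "implausible" is
a judgment call, two explicit rules are provided:

* `physical-range` (default): keep crossings in (0, 0.5] cm for DLG and
  (0, 0.05] for MLC-TF. The DLG bound reflects that reported clinical DLG
  values sit well below 0.5 cm; the MLC-TF bound is the same ratio to its
  reference value (0.02 · 2.5) since no separate convention exists.
* `mad`: keep crossings within k·MAD of the median (k = 3 default), for
  cohorts where no physical range is defensible.

## Synthetic data: what it does and does not emulate

The generators produce exactly the statistical structure the method
assumes:

* cohorts: d(case, s) ~ Normal(δ_s, σ_s²), independent across cases and
  structures, plus injected outliers at fixed cells; optional Student-t
  noise (df configurable) to stress the exclusion rule;
* sweeps: d(case, s, level) ~ Normal(slope_s · (level − crossing_s), σ_s²),
  annotated with machine parameters;
* paired grids: a reference dose law (constant or linear in x) and a
  local grid = scale · reference + offset, with rectangular structures, so
  every mean dose and percent difference has a closed form (scale k gives
  exactly 100·(k−1) % everywhere).

Default conditions mirror the cohorts the method was characterized on:
32 / 33 / 51 cases (head & neck, cervix, chest wall), 30 cases per sweep
level, per-structure offsets and σ of a few tenths of a percent up to ≈1 %
(σ set to one-sixth of a typical control-limit range), sweep slopes of
0.2–3.2 % per 0.1 cm DLG and 0.4–2.5 % per 0.01 MLC-TF, crossings at the
reference machine values, and optic structures given deliberately extreme
crossings (1.5–1.8× the plausibility bound) to exercise the outlier rule.

What the generators do **not** emulate: spatial dose distributions, beam
models, MLC sequencing, inter-structure correlation (in reality all
structures of one case share a calculation, so their differences are
correlated), autocorrelation over time, and non-Gaussian clinical tails
beyond the optional t noise. Passing tests therefore demonstrate that the
*statistics* are implemented correctly and recover known truth under the
assumed model — not that clinical cohorts satisfy that model, nor what
chart limits a given clinic should expect. Chart limits are
institution-specific by construction: they encode the local TPS and its
commissioning, so charts detect *changes* in a process, never the absolute
correctness of its commissioning.

## Problem sizes and tolerances in the test suite

Oracle-equivalence checks run on hundreds of short series (n ≤ 60) and
≤ 10³-voxel grids against independently coded brute-force loops, with
exact (10⁻¹² relative) agreement required. Coverage uses one 10⁵-point
in-control series (fraction outside limits 0.0027 ± 0.001). Rate recovery
uses 100 replicate seeded sweeps of 5 levels × 30 cases: the OLS 95 % CI
must cover generator truth for ≥ 90 % of fits, and at noise σ = 0.3 % the
fitted crossings must sit within ±0.01 cm of truth (their standard error
is ≈ 0.003 cm there). Drift detection requires 100 % flagging of a +5 %
shift over σ = 0.5 % charts across 20 replicates — a 10σ shift, so any
miss indicates a defect, not bad luck. All random tests are seeded;
hypothesis-based property tests run derandomized.

## Known limitations

* Mask construction is center-in with no partial-volume weighting; very
  small structures relative to the grid pitch are noisy (and can be empty,
  which is reported, not silently dropped).
* The exclusion fixed point is not guaranteed to exist for adversarial
  series (the retained set can in principle cycle); `max_iter` caps this
  and the non-convergence is logged. It has not been observed on random
  or clinical-like data.
* OLS on 4–5 levels has wide slope CIs; the zero crossing is an
  extrapolation when the levels lie to one side of it (as the default
  MLC-TF levels do), and its per-structure uncertainty is not propagated
  into the summary SD.
* DICOM support is read-only and intentionally narrow: axis-aligned RT
  Dose grids and planar RT Structure Set contours.
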