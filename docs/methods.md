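# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic data do and do not establish.

## COP extraction

The center of pressure is computed from plate channels with the standard
mechanics `ML = 1000·(−My − Fx·z0)/Fz`, `AP = 1000·(Mx − Fy·z0)/Fz` (mm),
where `z0` (m) is the vertical distance from the plate surface to the
torque reference. Commercial plates differ in where torques are
referenced; `z0` defaults to 0 (torques at the surface) and is exposed for
real hardware. Axis convention: ML = x (rightward positive), AP = y
(forward positive). `Fz ≤ 0` anywhere invalidates a stance trial (the
division is undefined without load), so it is rejected rather than masked.

## Preprocessing

Trials are windowed to the protocol length (`fs·duration`, 10,000 samples
at defaults) and filtered with a forward-backward Butterworth low-pass,
per-pass order 2, cutoff 5 Hz. "Zero-lag second-order" is read as the
per-pass order — the common reading in movement science — so the combined
magnitude response is 4th-order while the phase cancels. Edge transients
are suppressed by reflective (even) padding of
`min(9·(2·order + 1), n−1)` samples; on 50 s records this leaves the
steady state untouched. The forward-backward pass is time-symmetric in the
signal body but not bit-exactly in the first/last few dozen samples
(scipy's initial-condition scaling is one-sided); the property tests check
the interior. Spectral parameters intentionally use the *unfiltered*
series: a 5 Hz low-pass inside a 0.05–1.5 Hz analysis band would be
harmless, but the pipeline keeps the published processing split — filtered
data for spatial/nonlinear parameters, raw data for the PSD.

## Stability parameters

Sway path and per-axis excursions are plain first-difference sums. RMS is
the population SD (divisor n); at n = 10,000 the n−1 form differs by
<0.01%. The 95% ellipse uses the chi-square quantile form
(`k = χ²₂(0.95)`) on the sample covariance: it is the coverage region of
the point cloud, and at n = 10,000 the small-sample F-based variant is
indistinguishable (the two quantiles differ by <0.1%). Collinear clouds
raise an error instead of returning area 0, because the fractal dimension
divides by the ellipse-derived extent.

## Structure parameters

**ApEn.** Classic Pincus definition with delayed embedding: the lag
enters as the spacing between template components (not as decimation), the
tolerance is `0.2·SD` of the analysed (filtered) series, self-matches are
counted so `C_i ≥ 1/N` and no logarithm degenerates. The statistic is
therefore exactly invariant to affine rescaling of the input. The O(n²)
count is a compiled kernel; a brute-force template-counting oracle in the
test suite pins the implementation to ≤1e-10.

**FD.** The stabilogram fractal dimension `FD = ln N / ln(N·d/SP)` with
`d` the geometric-mean diameter of the 95% ellipse. The axes entering `d`
are read as semi-axes, giving `d = 2√(ab)`; a `full_axes` switch provides
the alternative reading (`4√(ab)`), which lowers FD by a constant shift of
the log denominator. FD = 1 for a straight segment (d = SP) and lies in
(1, 2) for physiological sway. Values outside [0, 2] — which rough,
noise-like trajectories do produce, since the formula is not clipped —
raise a warning, not an error.

**MPF.** Multitaper PSD with NW = 3 and K = 5 Slepian tapers (unstated in
the protocol this mirrors; K = 2·NW − 1 is the standard choice), FFT
length the next power of two, eigenspectra averaged unweighted. The native
grid is averaged into 0.025 Hz bins; with 50 s records the native
resolution (~0.012 Hz after padding) puts ≥1 native frequency in every
bin. The retained band is (0.05, 1.5] Hz by default: the first bin past DC
is excluded, and an `include_first_bin` switch restores 0.025 Hz. MPF is
the power-weighted mean over retained bins, hence always inside the band.
Note the reference study prints ApEn and MPF rows in units of n×10²;
this package reports natural units (dimensionless ApEn, Hz) and leaves
any display scaling to the caller.

## Mixed repeated-measures ANOVA

Balanced, fully crossed designs only: one between-subjects factor, any
number of within-subjects factors, one observation per subject per cell.
Unbalanced data are rejected with the missing cells named — the
sums-of-squares algebra is exact only for balanced data, and the study
design this serves is balanced by construction. Effect and error SS are
computed by inclusion-exclusion over marginal means; each within effect
(and its interaction with the group factor) is tested against its own
effect × subjects-within-groups interaction. A first-principles textbook
oracle in the test suite pins F to 1e-8.

Greenhouse-Geisser ε is estimated from the covariance of subject-level
cell means pooled *within groups* (the classical mixed-design estimator;
pingouin's one-way ε, which centers on grand cell means, agrees exactly
when groups coincide, and the test suite checks this case). ε is applied
to every within effect regardless of a sphericity pretest, which is the
conservative reporting convention; for 2-level factors ε = 1 identically.
The corrected p evaluates the same F at (ε·df₁, ε·df₂). This correction
is conservative wherever the test can reject; for F ≲ 1.4 (p ≥ 0.26)
shrinking the degrees of freedom can lower p marginally, which is
irrelevant to any decision at α = 0.05.

Partial eta squared is attached per effect as `F·df₁/(F·df₁+df₂)` with
uncorrected df (the convention under which published values are
recoverable from printed F and df). Post hoc paired t-tests multiply raw
p by the number of comparisons (capped at 1). Hedges `g_av` uses the
average of the two conditions' sample SDs and the small-sample correction
`J = 1 − 3/(4(n−1) − 1)` with df = n−1 — the paired-design convention of
the effect-size literature this follows; identical pairs report g = 0,
p = 1 rather than an undefined t. Shapiro-Wilk and Levene pretests are
available as diagnostics and never gate the analysis.

## Synthetic cohorts

Each axis is a stationary Ornstein-Uhlenbeck process, exactly discretised
and initialised at stationarity, so the stationary SD is the target sigma
from sample one and the PSD is a Lorentzian with corner
`bandwidth/2π ≈ 0.24 Hz` — dominant power well below 1.5 Hz, as in real
sway. OU was preferred over fractional Brownian motion because it is
stationary (bounded RMS, well-defined ellipse), has a closed-form target
SD, and keeps the spectral content low-frequency.

Defaults emulate the empirical magnitudes of the population the generator
stands in for: baseline `sigma_ap = 4 mm`, `sigma_ml = 2 mm` (control-like
RMS), respiratory sinusoid 0.3 mm at 0.25 Hz on AP, 5 subjects per group,
and multiplicative sigma contrasts — group ×1.6, eyes-closed ×1.2,
FP30 ×1.3, and an extra ×1.25 on patients' eyes-closed trials (the
group × vision interaction). Effects compose log-additively so they never
produce sign pathologies; per-subject intercepts on log-sigma
(SD 0.15) create between-subject variance. Seeding flows from one master
seed through `numpy.random.SeedSequence` spawning (PCG64), so cohorts are
bit-reproducible per seed and trial streams are independent.

What the generator does *not* emulate: intermittent postural corrections
(real sway is not Gauss-Markov), non-stationarity and fatigue drift,
heavy-tailed excursions, and any mechanistic link between muscle weakness
and sway. Passing calibration and recovery tests therefore establishes
that the pipeline detects amplitude contrasts of realistic size under
realistic spectra — not that it would reproduce clinical group differences
in structure parameters, which in the reference population were largely
null.

Simulation problem sizes: calibration suites use duration-preserving
scaled trials — 50 s at 10 Hz (500 samples) — which keep the number of
independent sway cycles per trial (and hence the per-trial metric
sampling noise) close to the full-rate protocol while making thousands of
replicate cohorts cheap. Full-rate (200 Hz, 10,000-sample) cohorts are
exercised end to end in the acceptance script and the worked example.

## Known limitations

- The ANOVA engine does not handle missing cells, covariates, or
  unbalanced groups; it is a faithful engine for the crossed balanced
  design, not a general linear-model replacement.
- ApEn cost is O(n²) per axis; at n = 10,000 a trial takes ~1 s on one
  core with the compiled kernel.
- The ellipse estimator assumes an approximately elliptical (unimodal)
  point cloud; strongly bimodal sway inflates the area.
- `read_forceplate_table` accepts delimited text only; vendor binaries
  (C3D etc.) are out of scope.
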