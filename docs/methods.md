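# Methods

## The measurement being modelled

A sonosensitive liposome suspension sits in a spectrofluorometer cuvette.
Encapsulated calcein is self-quenched, so fluorescence rises as cargo is
released and diluted; doxorubicin behaves analogously at its own
wavelengths. Low-frequency ultrasound (20 kHz in the reference protocol) is
applied in pulses — 20 s ON, 10 s OFF for calcein, 20 s OFF for doxorubicin
— because continuous insonation heats the cuvette and temperature interferes
with fluorescence. Sonication continues until the signal plateaus, then
Triton X-100 lysis releases everything and defines the maximal intensity.

Release is quantified as cumulative fractional release,
`CFR = (It − Io) / (I∞ − Io)`, with `Io` the mean over the pre-sonication
baseline and `I∞` the mean over the post-lysis plateau. CFR is exactly
invariant to detector gain and offset, which the tests assert.

Kinetic release laws describe CFR as a function of *insonation* time, so the
OFF segments (during which release is essentially frozen) are trimmed and
each ON sample is remapped to cumulative ON time ("de-stepping"). ON
intervals are treated as half-open `[on_start, on_end)`: a sample exactly on
the OFF transition belongs to OFF. This is deterministic, conserves sample
counts, and never double-counts ON time; a consequence is that a profile
sampled at rate `fs` spans `[0, total_ON − 1/fs]` rather than closing the
interval at `total_ON`.

## Model catalog

Eleven models are fitted (see the README for the formulas). Choices that
were genuinely open:

- **First-order** is parameterized as `A·(1 − exp(−k1·t))` with the
  amplitude ratio `A = C0/CT` fitted in (0, 1.5]; the common textbook
  rearrangement of the first-order law into CFR form is sign-ambiguous, and
  a fitted amplitude subsumes both readings.
- **Higuchi** is `kh·√t` — the square-root law; Korsmeyer–Peppas with
  `n = 0.5` reduces to it exactly (asserted pointwise in the tests).
- **Gompertz** is implemented as `kg·exp(−c·t^b)` with natural logarithm and
  the shape `b` unconstrained in sign (bounds [−5, 5]). Rising release
  curves require `b < 0`; the log-base choice only rescales `b`, so nothing
  is lost by fixing natural log. The form is singular at `t = 0`; samples at
  `t ≤ 0` are dropped before fitting and the count is recorded on the
  result.
- **Hopfenberg** `1 − (1 − k·t)^b` is only meaningful while `k·t < 1`;
  predictions beyond that point saturate at 1.
- **Hixson–Crowell** and **Baker–Lonsdale** are fitted after linearizing the
  response — `Y = (1 − CFR)^{1/3}` regressed on `1 − k·t`, and
  `Y = (3/2)[1 − (1 − CFR)^{2/3}] − CFR` on `k·t` — the standard practice
  for these two laws. Observed CFR values at or above 1 (possible under
  noise) are clamped to `1 − 1e−9` before transforming and the clamp count
  is reported. Both the fit-space SSE (what the regression minimized) and
  the CFR-space SSE (back-transformed predictions against observed CFR) are
  reported; cross-model comparisons use CFR space because fit-space SSEs of
  linearized and direct models are not commensurable.
- **Cubic polynomial** `p1·t³ + p2·t² + p3·t + p4` is solved by ordinary
  least squares on time rescaled to [0, 1] (conditioning). It is a
  goodness-of-fit benchmark with no mechanism, so best-model selection
  excludes it by default. It nests every non-negative-slope zero-order line,
  hence its SSE can never exceed the zero-order SSE — a dominance relation
  asserted in the tests. It needs at least four points (its parameter
  count); four distinct times interpolate exactly.
- **Korsmeyer–Peppas** is fitted to the full profile by default. The
  conventional restriction to the first 60% of release is available as
  `truncate_release=0.6`, off by default, because the reference analyses
  apply the power law to whole CFR curves.

## Fitting

Bounded trust-region nonlinear least squares (`scipy.optimize.least_squares`,
method `trf`) with function/step/gradient tolerances of 1e−10. Default
bounds and starts follow coefficient role: rate constants in [0, 100] with
start 0.01, exponents in [0, 5] with start 0.7, amplitude ratios in [0, 1.5]
with start 0.9; the Hixson–Crowell slope keeps a wide symmetric [−100, 100]
window with start 1, and the Gompertz shape is [−5, 5] with start −0.7. The
single documented start point is the default; a seeded multi-start option
(`multi_start=10`) exists for the flat likelihoods of Gompertz and
Hopfenberg. Fits are deterministic given identical inputs and options.
Non-convergence is flagged on the result, never raised, so a study over
hundreds of runs completes; only structural problems (too few points for
the parameter count) raise.

Ties in SSE across models break toward fewer parameters, then catalog
order.

## Plateau detection

`I∞` comes from the earliest maximal post-lysis interval whose rolling
least-squares slope of range-normalized intensity stays below a tolerance
(window 10 s, tolerance 1e−4 s⁻¹ by default). The slope estimate in a 10 s
window at 1 Hz has a standard deviation of roughly `σ_norm/√(w³·fs/12)` ≈
1e−3 at 1% noise — an order of magnitude above the tolerance — so at
realistic noise the detector declines and the documented fallback (the mean
over the final window seconds of the trace) supplies `I∞`. With ≥ 10
samples the fallback estimates `I∞` to ~0.3% of the dynamic range, which is
negligible against the fit residuals. At low noise the detector localizes
the plateau onset to within one window of the true lysis time (tested).

## Synthetic data generator

`simulate_trace` builds `intensity = Io + CFR_true(cumulative ON time)·(I∞ − Io)`
plus Gaussian noise on *intensity* (noise enters at the photodetector, not
in CFR), holds CFR during OFF (optionally with a small linear `off_leak_rate`
for residual inter-pulse release), steps to `I∞` at lysis, and appends a
flat plateau tail. Trace length is exactly
`baseline + n_cycles·(ON+OFF) + lysis_delay + plateau_tail` at any sampling
rate. A master seed spawns independent per-replicate streams
(`numpy.random.SeedSequence`), so studies are exactly reproducible.

Defaults: 60 s baseline, encapsulant-specific pulse schedule, 1 Hz sampling
(the acquisition rate of the emulated instrument is not documented, so it is
an explicit parameter; validation pins it), `Io = 100`, `I∞ = 1100`
arbitrary units, 10 s lysis delay, 30 s plateau tail. The reference study
layout is seven moieties × three power densities × nine replicates with
power-law ground truths taken from the bundled coefficient table and noise
SD of 1% of the dynamic range.

What the generator does **not** emulate: calcein self-quenching
nonlinearity, thermal drift during ON segments (available as an option,
default off, since pulsing exists to suppress it), cavitation physics, and
instrument-specific artifacts such as spikes or detector saturation.
Passing tests therefore demonstrate that the pipeline is correct and
well-conditioned under the protocol's statistical structure, not that any
particular laboratory dataset is free of systematic effects.

## Validation problem sizes

The deterministic recovery checks use 30-cycle (600 ON samples) and
10-cycle (200 ON samples) noiseless runs at 1 Hz; the Monte-Carlo study
uses the full 7 × 3 × 9 = 189-trace grid at 30 cycles with 1% intensity
noise, chosen to match the reference study design while keeping the whole
suite comfortably fast on one CPU. Under those conditions the median
relative error of the recovered power-law rate coefficient is below 5% and
the generating model wins CFR-space best-model selection in every
moiety × power cell.

## Known limitations

- Baker–Lonsdale's direct CFR form requires numerically inverting its
  response transform (Brent's method per time point); it is exact to 1e−14
  but slower than closed forms, which is irrelevant in fitting (the model is
  fitted in transform space) and minor in evaluation.
- The transport-mechanism thresholds are the spherical-geometry ones; film
  and cylinder thresholds are out of scope.
- An exponent landing exactly on a classification threshold is assigned to
  the lower class and flagged (`boundary=True`) rather than silently
  classified; strict inequalities are the printed convention for the
  anomalous band.
- Model selection is by SSE only, mirroring the analysis this package
  reimplements; SSE rewards flexibility, which is why the cubic is excluded
  from "best physical model" calls. Information criteria are deliberately
  not the headline statistic.
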