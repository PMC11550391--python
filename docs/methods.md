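# Methods

This note documents the models, algorithms and design choices behind
`hrid`, and what the synthetic experiments do and do not demonstrate.

## Model family and exact simulation

All structures are special cases of a continuous-time process model with
up to two real poles (`τ1`, `τ2` ≥ 0 s), one zero (`Tz`, sign-free,
seconds) and a dead time (`Td` ≥ 0 s), plus the parallel two-branch form
`P1parP1D` (branch gains `kp1`, `kp2`; time constants `τp1`, `τp2`; the
second branch delayed by `Td`). Gains are in bpm per m/s (treadmill, TM)
or bpm per W (cycle ergometer, CE). Parameters constrained to zero by a
structure are held at zero exactly.

Measured inputs are sampled every 5 s and treated as zero-order-held:
constant over each sampling interval. The simulator computes the exact
continuous-time response at the sample instants:

- The transfer function is decomposed into first-order modes (partial
  fractions). Each mode `x` obeys `τ x′ = u_d − x` with the delayed held
  input `u_d(t) = u(t − Td)` and has the exact discretisation
  `x(t+δ) = e^(−δ/τ) x(t) + (1 − e^(−δ/τ)) u_d` over any interval where
  `u_d` is constant.
- A fractional dead time `Td = m·h + r` (0 < r < h, sample period `h`)
  shifts the input's switch times off the sampling grid; each sampling
  interval then contains exactly two constant-input sub-intervals,
  `[jh, jh+r)` and `[jh+r, (j+1)h)`, and the state is propagated across
  both. The resulting one-step recursion is evaluated with
  `scipy.signal.lfilter`, so simulation is O(N) with no Python loop.
- The zero enters only through the modal output map (for one pole, a
  direct feedthrough `k·Tz/τ` plus a corrected mode gain); nothing ever
  differentiates the sampled signal.
- A repeated pole pair (`|τ1 − τ2| ≤ 1e−9·max`) uses the analytic
  Jordan-block propagator `e^{At} = e^{−t/τ} [[1, t/τ], [0, 1]]`, not a
  perturbation of the tied poles.
- Degenerate cases: with both time constants zero the model collapses to
  a (delayed) static gain and simulates as such; a zero with no poles
  would be improper under a held input and is rejected.
- Zero initial state is the default (records are analysed in deviation
  form, assumed to start at rest). An arbitrary initial modal state is
  supported; state coordinates are the unit-DC mode outputs.

The exactness claims are tested against closed-form step responses
(partial-fraction expansion evaluated in continuous time) and against an
independent ×100-oversampled dense-grid simulation built from
`scipy.signal.cont2discrete`; agreement is at machine precision, far
inside the 1e−6 / 1e−4 tolerances asserted.

## Preprocessing and the deviation representation

Records are analysed as deviations around mean levels. The default
profile only centres `u` and `y` over the evaluation period. Because the
initial minutes of a test show a slow drift, a recommended profile also
drops the first 300 s (covering drift time scales of roughly 140–180 s)
before centring; an optional least-squares linear detrend of `y` is
available (the detrending method is this package's choice). Steps always
apply in the order trim → centre → detrend, so means refer to the
retained period.

Consistently with this representation, the estimator also expresses the
*simulated* output as deviations around its own mean over the evaluation
period before comparison (`center_sim=True`). This removes the arbitrary
offset between a simulation started from rest and empirically centred
measurements; without it, even noise-free data generated by the package's
own models could not be fitted to 100 %. The same centring is applied to
the simulated output on the validation record.

## Estimation

Free parameters are estimated by minimising the sum of squared output
errors with `scipy.optimize.least_squares` (trust-region reflective,
finite-difference Jacobian) under box constraints. Default bounds —
declared package choices, config-overridable — are: time constants
[1, 600] s, dead time [0, 60] s, zero [−120, 120] s, gains [0, 100]
bpm/(m/s) for TM and [0, 2] bpm/W for CE; they comfortably contain all
parameter values the package's own experiments produce.

Dead time is a continuous decision variable inside the search, which
creates local minima; a multi-start scheme mitigates them: one start at
the midpoint of the bounds plus seeded random draws (log-uniform for
time constants and dead time, uniform for gains and the zero), 10 starts
by default. Convergence tolerance is 1e−10 on the relative objective
decrease, at most 500 objective evaluations per start. The best local
optimum over starts is returned together with the number of converged
starts and the seed. Exchangeable pole pairs are reported canonically as
`τ1 ≤ τ2`. Optionally the initial modal state can be appended to the
decision vector (`estimate_x0`); it is off by default because the
deviation representation plus transient trimming is the intended way to
handle start-up effects.

The fit metric is `100·(1 − ‖y − ysim‖₂/‖y − ȳ‖₂)`, the normalised
root-mean-square error convention of standard system-identification
toolboxes; a sum-of-squares variant (`fit_formula="ssq"`, both norms
squared) is available for sensitivity checks. The metric is undefined
for constant `y` and translation-invariant.

Counterbalanced cross-validation: within each subject's pair, the model
estimated on test 1 is simulated against test 2's input and scored on
test 2's output (and vice versa), always from zero initial state on the
validation record. Structure comparisons aggregate the arithmetic mean
of validation fits over all records of a modality (both directions, one
per record); no significance testing is performed.

## Synthetic data

The generator emulates the paired PRBS experiments the analysis is built
for:

- **PRBS**: maximal-length shift-register sequences (orders 3–16, known
  primitive taps), two levels held for a clock period. Defaults: 30 s
  clock, order 7, 1800 s duration at 5 s sampling — an excitation whose
  bandwidth brackets 30–180 s time constants. The seed selects the
  (never all-zero) initial register state.
- **Truth**: the two-phase parallel model, drift branch slow and
  low-gain, response branch delayed and dominant. Cohort truths are
  drawn with ±20 % uniform jitter around the estimates obtained on the
  real cohorts (TM: 20.2 bpm/(m/s), 34.3 s, 17.9 s fast; 7.0 bpm/(m/s),
  141.5 s drift. CE: 0.35 bpm/W, 37.9 s, 17.1 s; 0.09 bpm/W, 180.7 s).
  Input levels (1.2–2.0 m/s; 75–125 W) and baselines (140 / 120 bpm)
  are chosen to give moderate-to-vigorous intensities and heart-rate
  swings of realistic size (~±10 bpm); the original studies' PRBS
  designs and levels are not published, so these are declared emulation
  choices.
- **Noise**: white Gaussian at the sample level, default σ = 2 bpm. The
  two tests of a pair share truth and input but have independent noise
  streams, seeded by (subject seed, test index).
- Drift is generated as the slow branch's response to the input, not as
  an exogenous ramp; an optional additive ramp (bpm/min) exists to
  stress the detrending stage.

What the generator does *not* model: autocorrelated heart-rate
variability, respiratory oscillations, above-anaerobic-threshold
nonlinear drift, sensor dropouts, or between-test differences in the
input realisation. Passing recovery tests therefore demonstrates the
correctness and conditioning of the estimation machinery under the
stated assumptions, not robustness of the model family on measured
human data.

## Synthetic experiment design and observed behaviour

Problem sizes are chosen to mirror the design of the motivating studies:
cohorts of 11 treadmill subjects (22 records) and 27 cycle-ergometer
subjects (54 records), 1800 s records, 5 s sampling, 10 optimiser starts.
The test suite uses these sizes directly; they run in seconds to a few
minutes on one core because simulation is closed-form.

Reproducible observations from the package's own experiments (computed
by `scripts/acceptance.py` and the test suite, not asserted as facts
about human data):

- Noise-free recovery is exact to optimiser tolerance for all seven
  structures; with σ = 2 bpm, median relative errors for first-order-
  plus-dead-time parameters are a few percent.
- Within a pair, the mean cross-validated fit falls below the mean
  estimation fit in essentially every pair. The *within-pair* mean is
  the right comparison: a single direction's difference is dominated by
  the two tests' different noise realisations, which cancel in the pair
  mean.
- Mean validation fits order as expected when the truth is two-phase:
  plain first order is far behind, adding dead time recovers most of the
  gap, and the parallel form sits at or slightly above the delayed
  first-order model. The drift branch itself is weakly identified (its
  time constant is the least excited direction), which mirrors the
  instability of drift-component estimates reported for the measured
  cohorts.

## Numerical details and tie-breaks

- Dead-time split: the fractional part is snapped to the grid when
  within 1e−9 of a sample period, avoiding spurious sub-intervals.
- Pole tie: repeated-root propagator for `|τ1 − τ2| ≤ 1e−9·max(τ1, τ2)`.
- CSV I/O writes floats in shortest round-trip representation and reads
  them with round-trip parsing, so write→read is bit-exact.
- All cohort / noise / optimiser randomness flows from integer seeds
  through `numpy.random.default_rng`; pipeline seeds are derived per
  (subject, structure) with a CRC so results are independent of
  execution order, and report files contain no timestamps, making reruns
  byte-identical.

## Known limitations

- The estimation bounds and optimizer settings are package defaults, not
  values recovered from the motivating studies (which did not publish
  them); conclusions can shift if bounds exclude the true optimum.
- The parallel structure's advantage over delayed first order on
  validation data is small and can depend on the cohort realisation;
  the package reports both estimation and validation fits so such
  inversions stay observable.
- Only single-input, linear, time-invariant models are supported; no
  frequency-domain estimation, no confidence intervals on parameters.
- The canonical CSV + YAML sidecar format is this package's own; it does
  not parse the public repositories' native packaging.
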