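# Methods

This note documents the models implemented in `monpool`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal processing conventions

All derived signals live on the recording grid (2048 Hz by default), so
binarizing discharge times is lossless to one sample. Two discharges of one
unit falling on the same sample are rejected by default (physiologically
impossible at this rate); a merge flag exists for degraded inputs.

**Smoothed discharge rate (FIDF).** The instantaneous discharge frequency
(IDF) is an impulse train: the reciprocal inter-spike interval placed at the
left edge of each interval. Its 400 ms Hanning "moving average" is
implemented as a kernel-weighted average of the discharge-rate values — the
ratio of two Hanning convolutions, one of the rate impulses and one of the
spike indicator. Plain convolution of a rate-valued impulse train cannot
return a rate (its output scales with rate squared over the sampling rate);
the normalized form maps a periodic train to its own rate, which is the
property the rest of the workflow relies on, and keeps the output in Hz.
Where the denominator vanishes (no discharges within the window) the FIDF
is zero.

**Rate trendline.** The sixth-order polynomial trend is fitted to the
(time, rate) pairs at firing instants only, on a centred/scaled abscissa for
conditioning, and evaluated over the firing span. With fewer than
`order + 1` firing samples the order is reduced with a warning.

**Band-limiting.** All [0; f] Hz operations (CSI at 10 Hz, CSC/eND at 4 Hz)
use a 4th-order Butterworth filter applied forward–backward
(`sosfiltfilt`), which is zero-phase and preserves DC. The filter family
and order are package choices; both band edges are config keys.

**Agreement metrics.** `nRMSE = RMS(a−b)/range(b)·100`,
`nME = max|a−b|/range(b)·100`, and `r² = 1 − SS_res/SS_tot` (coefficient of
determination of `a` against reference `b`), computed on the overlapping
support. This r² is stricter than a squared Pearson correlation: it
penalizes scale and offset errors, not just shape errors.

## Threshold mapping

The linear-exponential threshold distribution is least-squares fitted
(`scipy.optimize.curve_fit`) to a step function that assigns each pool index
the midpoint of its 10 %MVC occupancy bin, with the boundary targets
`F^th(1)` and `F^th(N)` included as fit points weighted 100× a bin point —
strong enough to pin the ends without making the system inconsistent when
the bin data and the boundary fold-range disagree. The packaged tibialis
anterior bin fractions are reconstructed from the fitted distribution's own
printed coefficients (the underlying literature scatter is not
redistributable); fitting them back recovers those coefficients to within a
few percent, and the same code accepts user-supplied bin tables. The
gastrocnemius medialis reuses the TA distribution — no GM threshold dataset
of sufficient size exists.

Mapping inverts the fitted distribution by bracketed root finding
(`brentq`) and rounds to the nearest integer index; thresholds below
`F^th(1)` clamp to index 1 with a warning, duplicates receive consecutive
indices so the map stays injective (later stages assign per-index
parameters), and order is always preserved.

## Common input and current

The representativeness check splits the sample into complementary halves 20
times (seeded permutations; an odd sample drops one train per permutation),
computes magnitude-squared coherence between the half cumulative spike
trains (Welch, 1 s Hann segments, 50% overlap) and averages the bins in
[1; 10] Hz. Extrapolation from the half-sample to the full sample inverts
the composite-coherence relation `C_k = kγ/(1+(k−1)γ)` at `k = N_r/2` for
the per-unit common-input coherence γ and re-evaluates it at `k = N_r`.
This analytic rule is a documented approximation standing in for a
published empirical curve; it is conservative for strongly coherent
samples. The sample is called representative when the extrapolated
coherence exceeds 0.7 and the normalized common synaptic control tracks the
normalized force with r² > 0.7 and nRMSE < 30%; failure produces a
prominent warning but does not stop the workflow.

The current input uses the anchored-affine form
`I(t) = I^th_{N1} + G·(CSI(t) − CSI(ft¹_{N1}))` with
`G = (I^th_{Nr} − I^th_{N1}) / (CSI(ft¹_{Nr}) − CSI(ft¹_{N1}))`. Written
this way both anchor equalities hold exactly for any CSI normalization; the
plain form `I^th_{N1} + G·CSI(t)` is recovered when the CSI is zero at
onset. `I(t)` is zero before the first identified discharge (the sample
carries no information there), which is the workflow's main known blind
spot for samples missing the low-threshold pool.

## LIF neuron

Parameters derive from the membrane surface area `S`: `R = k_R/S^2.43`,
`C = C_m·S` (`C_m = 1.3 μF/cm²`), `τ = RC`, and `I^th = ΔV_th/R`
(`ΔV_th = 27 mV`, Ohm's law). The resistance scale `k_R` is anchored at a
mid-range reference unit (`R = 2 MΩ` at `S = 2.5e-7 m²`), which reproduces
the canonical 0.5–4.1 MΩ resistance span across the canonical size span;
`k_R` is a config key. Size monotonically orders rheobase, so recruitment
order under a rising common drive is the size principle by construction.

Integration uses the discrete recurrence
`V[n] = e^{−dt/τ}V[n−1] + (R·dt/τ)·I[n]` at `dt = 1e-4 s` (the default;
any `dt ≤ 1e-3 s` is accepted). An exact exponential-integrator variant
(coefficient `R(1−e^{−dt/τ})`) is provided for cross-checks; at the default
step the two agree in subthreshold voltage to better than 1% for
`τ ≥ 5 ms`. A spike is recorded at the grid sample where `V ≥ ΔV_th`
(no sub-step interpolation), the membrane is reset and held for the inert
period `IP`; with inert-period noise enabled, each hold is `IP + o`,
`o ~ N(0, IP/10)` truncated at `−IP` so the refractory time is never
negative. The per-sample loop is compiled with numba; per-unit random
streams are derived from a master seed by a counter scheme so enlarging a
pool never perturbs existing units.

During the derecruitment phase (from `t_tr3`) the apparent resistance is
raised to `R^d = R/k^dth` (so units stop firing at `k^dth < 1` times their
recruitment current — the hysteresis attributed to persistent inward
currents) and the specific capacitance to `C_m^d` (lower firing rates near
derecruitment). Both are phenomenological: they reproduce the macroscopic
hysteresis, not its biophysics.

## Calibration

A unit *saturates* when its rate trendline exceeds 90% of its mean plateau
rate anywhere in `[t_tr1, t_tr2 − 1 s]`; its inert period is then the
reciprocal of the trendline maximum. `IP(j) = a·j^b` is fitted in log–log
space to the saturating units' pairs (config accepts auxiliary anchor pairs
for sparse samples; with fewer than two saturating units the fit aborts
with that instruction). Non-saturating units take `IP(N_i)` from the
trendline.

The size objective — RMS difference between simulated and experimental FIDF
over `[t_tr0, (t_tr2+t_tr3)/2]` — is minimized by bounded Brent search over
`S ∈ [1.0e-7, 5.0e-7] m²` with inert-period noise disabled so the objective
is deterministic; grid scans on fixtures show a single basin. Per-unit
agreement metrics (`Δft¹`, nRMSE, r²) are reported over `[t_tr0, t_tr3]`.
`S(j) = S_min·Δ_S^((j/N)^c)` is fitted with `Δ_S` fixed (default 2.4).
A caveat discovered on synthetic data: the coefficient pair `(S_min, c)` is
poorly identified from a high-threshold-biased subsample — the fitted curve
is stable over the sampled range while the coefficients can trade off
substantially, and units recruited within a few percent of the plateau
current calibrate with large errors. Coefficient-level comparisons should
use well-spread samples.

The derecruitment ratio `k^dth` is the zero-intercept least-squares slope
of derecruitment versus recruitment currents (current at last versus first
discharge), clipped below 1 with a warning. `C_m^d` is selected by grid
search (0.1 μF/cm² steps up to 3.0 μF/cm²), scoring
`J = (mean nRMSE + 100·(1 − mean r²))/2` over `[t_tr3, t_tr5]` — an
equal-weight combination on a common 0–100 scale, chosen because the
published form of this score is typographically ambiguous; a boundary
optimum warns.

## Synthetic ground truth

The generator emulates the structure of trapezoidal HDEMG experiments:

- **Pool.** Thresholds follow the TA distribution; rheobases follow the
  9.1-fold distribution; the truth pool is built *self-consistently from
  the rheobase distribution* (`R(j) = ΔV_th/I^th(j)`,
  `S(j) = (k_R/R)^{1/2.43}`), which makes the size distribution exactly the
  power family with `Δ_S = 9.1^{1/2.43} ≈ 2.48` and `c = 1.18`. The
  published rheobase and resistance ranges are mutually inconsistent under
  strict Ohm's law; anchoring the truth on the rheobase side keeps the
  generator's current scale commensurate with the estimation pipeline's
  anchors, so recovery questions are well-posed. Inert periods follow
  `0.04·j^0.06` s; derecruitment uses `k^dth = 0.9`, `C_m^d = 2.0 μF/cm²`.
- **Drive.** The subject tracks a linear force ramp, so the common current
  is warped through the recruitment model:
  `I(t) = I^th(F^th⁻¹(F(t)))` — unit j is recruited exactly when the force
  crosses its threshold, and the plateau recruits exactly the pool fraction
  the threshold distribution implies at the plateau %MVC. A common
  fluctuation (10% relative SD, low-passed to [0; 10] Hz, seeded) rides on
  the drive; this level reproduces half-sample CST coherences around 0.5–0.6,
  matching trapezoidal HDEMG recordings.
- **Force proxy.** The "experimental force" is the truth drive through a
  1 Hz low-pass (muscle twitch filtering), scaled to the plateau %MVC —
  plateau force variability comes out near 3%, slightly above transducer
  recordings at this contraction level.
- **Identified sample.** Unit j is drawn without replacement with
  probability ∝ `(j/N)^β` (default β = 2) among units that fire tonically
  through the plateau (≥ 10 discharges, mean plateau rate ≥ 6 Hz, no silent
  plateau gap over 0.5 s) — intermittent, fluctuation-driven sources near
  the plateau recruitment margin cannot be separated by real decomposition.
  Recorded thresholds are the true `F^th(j)` (optionally jittered).

What the generator does **not** emulate: decomposition errors (missed or
false discharges), unit-specific synaptic noise (only the common
fluctuation and inert-period noise are stochastic), nonlinear
persistent-inward-current amplification of the drive, fatigue, and any
non-isometric behaviour. Consequently, passing fixture tests demonstrates
the pipeline's internal consistency and its behaviour under the documented
statistical structure — not robustness to decomposition artefacts.

A structural property worth stating plainly: the current-reconstruction
step assumes the true drive is affine in the sample CSI. In the generator
the true drive is constructed independently of that assumption, so the
estimated current carries a smooth mid-ramp error that the size calibration
absorbs; the reconstructed pool then reproduces drives and forces well
(self-consistently), while *per-unit recruitment instants* read off the
smoothed `S(j)` distribution inherit second-scale errors on slow ramps.
Leave-one-out rate and shape metrics are therefore much stronger than
leave-one-out recruitment-time metrics on this generator, and the same
asymmetry should be expected on any data whose drive deviates from
CSI-affinity.

## Muscle stage

Each motor unit's spike train drives two first-order stages: a normalized
calcium concentration receiving a saturating increment (gain 0.35) per
discharge with 60 ms decay, and a calcium–troponin stage with binding rate
40 s⁻¹ (scaled by calcium) and unbinding rate 10 s⁻¹. The active state is
a Michaelis–Menten-type saturation of the bound fraction (shape 0.2). These
constants are modelling choices giving a ~50 ms twitch rise and near-fusion
at 100 Hz; they are config parameters, not measured values. At optimal
length with force–velocity, tendon and passive elements omitted, unit force
is `f_iso^max(j)·a_j(t)` and muscle force is the plain sum; `f_iso^max(j)`
defaults to a 100-fold exponential across the pool normalized to unit total.

## Problem sizes

The test suite and examples run the reference configuration at full scale —
a 400-unit pool over a 30 s protocol at 2048 Hz, LIF integration at
`dt = 1e-4 s` — with one fit plus one pool simulation in roughly half a
minute; leave-one-out repeats the fit per held-out unit and is the one
long-running analysis (a few minutes for a 20-unit sample).

## Known limitations

- The drive before the first identified discharge is unobservable; samples
  missing the low-threshold pool produce a delayed drive onset.
- `(S_min, c)` coefficient identifiability from biased subsamples (above).
- The half-to-full coherence extrapolation is an analytic approximation.
- The LIF + apparent-parameter treatment of saturation and hysteresis is
  phenomenological; parameter values should not be read as biophysics.
- The muscle stage's excitation–contraction constants are plausible
  defaults, not fitted to any recording.
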