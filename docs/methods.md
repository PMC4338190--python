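# Methods

This note documents the models, estimators and numerical choices behind
`critslow`, and what the synthetic data can and cannot establish.

## Model systems

The two robust routes from neuronal quiescence to repetitive spiking are a
saddle-node (fold) bifurcation and a subcritical Hopf bifurcation. Close to
either, every neuron model reduces to the corresponding normal form, so the
package simulates the normal forms directly and treats everything else
(units, protocols) as affine maps, which power-law exponents are invariant
under.

**Saddle-node form.**  dV = (−y + ρV²)dt + σ₁dW + impulses, dy = −ε dt.
For y > 0 the stable equilibrium V⁻ = −√(y/ρ) coexists with an unstable one
at +√(y/ρ); they collide at y = 0. Linearizing about V⁻ gives the recovery
rate λ = 2√(ρy) and, with additive white noise, the stationary variance
σ₁²/(2λ) — hence the exponent pair (θ, τ) = (0.5, −0.5) in the distance y.

**Subcritical Hopf form.**  dV₁ = (yV₁ − V₂ + V₁(V₁²+V₂²))dt + σ₁dW₁,
dV₂ = (V₁ + yV₂ + V₂(V₁²+V₂²))dt + σ₂dW₂, with impulses applied to both
components and the control parameter ramped toward the bifurcation,
y(t) = y0 + εt from y0 < 0. The stable focus at the origin has eigenvalues
y ± i, so λ = |y| and (for σ₁ = σ₂ = σ) the stationary covariance of the
linearization is isotropic, σ²/(2|y|)·I — the exponent pair (1, −1). The
noise is independent per component; driving both components with the *same*
increments would make the stationary variance
σ²[1/|y| + (|y|−1)/(y²+1)], which is not a power law over the simulated
range and contradicts the −1 scaling the pipeline is meant to exhibit.

Defaults are the published study conditions: saddle-node (y0, V0) =
(1.6, −4), ε = 0.001, ρ = 0.1, σ₁ = 0.001, impulse 0.1 every 60 time units,
crossing at t_c = y0/ε = 1600; Hopf start (0, 0, −2), ε = 0.001,
σ₁,₂ = 0.001, impulse 0.005 every 60, t_c = 2000. An alternative strongly
driven Hopf set (ε = 0.02, σ = 0.01, impulse 0.05) is selectable.

## Integration and numerical choices

* Explicit Euler–Maruyama at fixed dt = 0.006 (both systems), chosen so one
  60-time-unit inter-pulse interval holds exactly 10 000 samples: 5000
  pre-pulse statistics samples plus 5000 post-pulse fit samples. The
  analyses need only first-order pathwise accuracy; the zero-noise tests
  verify convergence to the analytic equilibria to 1e−8 and pulse decays to
  within 2 % of the linearized rate.
* Impulses are instantaneous additive state kicks at t_i, 2t_i, …; the
  sample at the pulse time already contains the kick, and fit windows start
  one sample later.
* Escape (the "spike") is declared when the saddle-node state passes the
  unstable branch + 1 or |V| exceeds a bound, and when the Hopf radius
  exceeds max(2√(−y), 0.5). Normal forms diverge in finite time, so some
  bound is required; results are insensitive to it because all windows end
  before escape.
* One seeded `numpy` generator per trajectory; identical configs give
  bit-identical paths. File writers pin float formatting (9 significant
  digits) so repeated runs are byte-identical.

## Marker estimation

Per perturbation delivered before onset:

* **Recovery rate** — nonlinear least squares of a·e^(−λt) + b on the
  post-pulse window after subtracting the segment mean, λ bounded to
  (0, Nyquist). Initialization is scale-free (b from the last decile,
  a from the first sample, λ = 5/window); non-convergent fits are kept as
  missing-λ samples so the variance/ACF series stay full length.
* **Variance** — population convention (divide by N) on the unperturbed
  pre-pulse segment.
* **Autocorrelation** — ACF\*(s) = Σ(F(t)−μ)(F(t+s)−μ)/v normalized by
  ACF\*(1), so ACF(1) ≡ 1. The lag-1 normalization is unstable when a
  segment is white-noise dominated; a guard raises instead of returning
  noise. Default lags: 100 samples (model units), 50 ms (recordings).
* **Distance to the bifurcation** — y (saddle-node) or −y (Hopf) at the
  pulse time for model data; I_c − ⟨I⟩_pre for recordings, with I_c the
  mean current over the second before the first spike.

Saddle-node trajectories are detrended by subtracting the moving stable
branch before any statistic is computed; the Hopf equilibrium is the origin,
so no detrending is needed.

**Hopf recovery fits use the radius √(V₁²+V₂²), over the same 5000-sample
window as the saddle-node fits.** This is a deliberate estimator choice.
The linearized Hopf flow is a rotation (period 2π) times e^(−|y|t): the
radius decays as a clean exponential, while V₁ itself crosses zero within
any fit window longer than a quarter period, so an exponential fit to V₁
measures the rotation rather than the damping (on the noise-free
linearization it returns rates scaling as |y|^0.5). A short window does not
fix this: whatever the sampling step, a window of duration T gives the rate
estimator an absolute noise floor ≈ 1/T, which swamps the vanishing rates
near the bifurcation — the estimator is only valid while λ·T ≳ 1. Fitting
the radius over the full half-interval window satisfies both constraints
and recovers the expected exponent (mean θ = 0.99 ± 0.18 over 20 seeds).

Windows for emulated recordings follow the experimental convention: 1 s
pre-pulse segments, 4800-sample (192 ms at 25 kHz) post-pulse fit windows
starting after the 5 ms pulse. Events whose windows would cross the onset,
another pulse, or the recording edge are dropped and counted.

## Patch-protocol emulation

The emulator binds the saddle-node dynamics to the experimental staircase
protocol rather than simulating a conductance-based neuron:

* The control parameter follows the staircase: each 3 pA step decrements y
  by Δy = ε·time_scale·step_duration, so ΔI ∝ y by construction and the
  pA↔y scale cannot be configured inconsistently with the drift.
* Model time runs at `time_scale` = 30 time units per protocol second, one
  Euler step per 25 kHz voltage sample, which makes the ~2 s pulse spacing
  correspond to the model's 60-time-unit spacing.
* The recorded voltage is V_rest + R·I_step(t) + scale·V_d(t), with V_d the
  fluctuation about the stable branch. The ohmic term (default R = 0.9
  mV/pA) emulates the passive depolarisation that dominates a real
  recording; it makes the recorded voltage approximately affine in the
  injected current, so the voltage-space recovery-rate law for a saddle-node
  is λ ∝ (V_c − V)^0.5 — the relation the tipping-point predictor exploits.
  With R = 0 the voltage is a purely affine readout of the normal-form
  state, in which case V_c − V ∝ √ΔI and the voltage-space exponent is 1.
* Onset is the first upward crossing of the spike threshold (0 mV); the
  normal form's finite-time divergence supplies the upswing. The ramp stops
  there, as in the experiment.
* Control mode holds y fixed at y0 while the staircase still ramps,
  emulating a sodium-channel-blocked cell: the staircase, pulses and
  windows are identical but the dynamics carry no slowing-down trend, and
  the nominal critical current from the mapping is carried in provenance so
  the downstream fit can still be formed (and rejected).

Prediction batches draw per-trial cell parameters — input resistance
N(0.9, 0.1) mV/pA clipped to [0.6, 1.2], resting potential N(−70, 2) mV,
y0 N(1.6, 0.15) clipped to [1.2, 2.0], σ₁ lognormal(ln 10⁻³, 0.25) —
because real across-trial regressions pool different cells; with identical
cells the measured distance to threshold has essentially no across-trial
variance and the regression is undefined.

## Scaling fits and classification

Exponents come from OLS of log x on log ΔI (plain, unweighted), excluding
nonpositive distances, missing rates and nonpositive marker values;
fits need ≥ 5 points and are rejected when R² < 0.1. The fit is repeated
over 8 logarithmically spaced cutoffs ΔI_min between the 5th and 60th
percentiles of the observed positive distances (the grid is configurable
and recorded in outputs); the reported exponent is the mean over accepted
fits, its spread the sd. Classification is nearest-template in (θ, τ)
space against (0.5, −0.5) and (1, −1), declared indeterminate when the
templates are equidistant, when θ and τ disagree about the nearer template,
or when the nearest template is farther than 0.35 (configurable). κ is
reported but never classified: it depends on the autocorrelation lag.

## Tipping-point prediction

λ = a·(V_cp − V)^θ is fit in plain λ space with θ held fixed and (a, V_cp)
free, after dropping the n_exclude = 5 rate samples nearest onset;
V_cp is constrained to (V_last, V_last + 50 mV] with a scale-free
initialization (these optimizer details are the package's own — exact
recovery on noiseless data to 1e−6 is tested for arbitrary θ). ΔV_p =
V_cp − V_last is compared with ΔV_m = V_cm − V_last by ordinary linear
regression across trials; the governing exponent yields a significant
positive regression while a misspecified one degrades it.

## Problem sizes and what the tests show

The validation suite uses 20 independent trials per model system (each
~270 000–340 000 integration steps), 5 batches of 20 heterogeneous emulated
recordings (~1.4 million samples each) for the prediction contrast, and
5 control recordings; these sizes keep the whole suite and the acceptance
script to a few minutes while leaving the Monte-Carlo error of the reported
means well inside the asserted bands.

Passing on this synthetic corpus shows that the estimators recover the
known scaling of the normal forms under realistic protocol structure,
noise, drift and truncation — it does not establish anything about features
of real recordings the generator does not emulate: channel noise that is
neither additive nor white, electrode/filtering artifacts, slow adaptation
or bursting that moves the bifurcation during the ramp, synaptic
bombardment, or cell-to-cell variability beyond the four parameters the
batch generator varies. The emulated voltage map is affine plus an ohmic
ramp; real I–V curves bend near threshold, which would shift voltage-space
(not current-space) exponents. Exponent recovery, not exponent discovery,
is the claim being tested.

## Known limitations

* The no-bifurcation control emulates only the *dynamical* consequence of
  sodium-channel block (no approach to the bifurcation), not its
  pharmacology.
* Near the crossing, recovery-rate estimates are validity-limited by
  λ·window ≳ 1; the cutoff sweep's lower percentiles deliberately exclude
  the worst of this region, and the spread over the sweep is reported.
* The Hopf emulation is not wired into the patch protocol (the experiment
  this package mirrors identified saddle-node scaling in both neuron
  types); Hopf analyses run in model units.
* Prediction is implemented from the recovery rate only, not from variance
  or autocorrelation.
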