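# Methods

## The model

The package fits a phenomenological model of spike-threshold adaptation to
intracellular voltage traces.  The dynamic threshold θ(t) relaxes toward a
voltage-dependent steady state with a single time constant,

    τ_θ dθ/dt = θ∞(V(t)) − θ,

and a spike is predicted the instant the membrane potential reaches the
threshold, followed by a 0.5 ms refractory period during which no further
spike is emitted.  The threshold itself is never reset: in the recordings
this model was developed for, no correlation between interspike interval
and measured threshold is observed, so a post-spike threshold increment
buys nothing.

The steady-state curve is a softplus interpolation between two asymptotic
slopes,

    θ∞(V) = θ₀ + α(V − V_i) + (β − α)·k_a·ln(1 + exp((V − V_i)/k_a)),

near-constant (slope α ≈ 0) below the critical voltage V_i and rising with
slope β ≈ 1 above it, with the sharpness of the bend set by k_a.  This is
the minimal smooth curve with the properties predicted by sodium-channel
inactivation: below the half-inactivation voltage the available sodium
conductance, and hence the threshold, barely depends on V; above it the
threshold rises roughly one-for-one with V.  The six scalars
(τ_θ, V_i, θ₀, α, β, k_a) are the fit target.

Numerics: ln(1+eˣ) is computed as x + ln(1+e⁻ˣ) for x > 0; the ODE is
integrated with the exact exponential update per sample (V held constant
over each sampling interval), which is unconditionally stable even when
τ_θ is far below the sampling interval — fitted time constants in this
preparation are a few hundred microseconds, close to the 24–42 kHz
sampling intervals, where explicit Euler would be marginal.  θ(0) is set
to θ∞(V(0)), which removes the arbitrary initial transient; the first
max(5 τ_θ, 5 ms) of every trace is excluded from all scoring.

## Measured spike threshold

The empirical threshold of a recorded spike is the voltage at its onset:
scanning backward from each spike peak (peaks gated by 10 mV prominence),
the onset is the start of the contiguous stretch over which the centered
finite-difference dV/dt stays above a fixed criterion, 25 mV/ms — i.e. the
upward crossing of the criterion nearest the peak.  No smoothing is
applied: at 24–42 kHz the upstroke derivative is well resolved, and
smoothing would bias the onset voltage downward.  Per spike the package
also reports the mean voltage in the 5 ms before onset, the least-squares
depolarization slope over the preceding 1.5 ms, and the preceding
interspike interval, together with the Pearson correlations and
regression slopes of onset voltage against each of these predictors.

## Scores

**Gamma coincidence factor.**  Γ counts one-to-one coincidences between
recorded and predicted spike trains within a half-window δ (default
84 µs, about two samples at 24 kHz), corrects for the coincidences a
Poisson train at the recorded rate ν would produce by chance, and
normalizes so a perfect prediction scores 1:

    Γ = 1/(1 − 2νδ) · (N_coinc − 2νδ N_pred) / ((N_rec + N_pred)/2).

Coincidence matching is a greedy earliest-first sweep over both sorted
trains; for interval-overlap graphs of this form the greedy sweep attains
the maximum-cardinality matching (property-tested against exhaustive
matching on all small instances).  |Δt| ≤ δ counts as coincident; ν is
taken from the recorded train.

**False alarms and explained variance.**  The false-alarm rate is the
percentage of recorded spikes represented by unmatched predictions,
100·(N_pred − N_coinc)/N_rec.  The explained variance compares the
model's threshold at coincidence-matched onsets with the measured onset
voltages: EV = 1 − Σ(θ̂ᵢ−θᵢ)²/Σ(θᵢ−θ̄)².

**Curve distances.**  Fits from different conditions are compared by the
voltage-averaged absolute difference between their steady-state curves
over the sub-threshold voltage range of the data (trapezoidal rule, 1000
points), and against the diagonal θ = V.

## Fitting

CMA-ES maximizes the mean Γ across the traces of a subset over the six
parameters, with τ_θ searched in log₁₀ coordinates.  The optimizer is a
self-contained (μ/μ_w, λ) implementation with rank-one and rank-μ
covariance updates and cumulative step-size adaptation; box constraints
are enforced by projection with a quadratic penalty on the projection
distance, so the objective is only evaluated at feasible points.
Defaults: population 16, 3000 objective evaluations in total, σ₀ = 0.3 of
the box width, 2 restarts, fixed seed.  Search bounds bracket every value
reported for this preparation: τ_θ ∈ [0.05, 20] ms, V_i and θ₀ ∈
[−80, −40] mV, α ∈ [0, 1], β ∈ [0, 2], k_a ∈ [0.5, 20] mV.  The search
starts from a data-informed guess — the offset near the low edge of the
measured onset-voltage distribution, the knee just above the bulk of the
sub-threshold voltage — which practitioners would use and which roughly
halves the budget needed for convergence.  The objective's inner loop
(steady-state lookup, exponential update, crossing detection with
refractoriness) is a single compiled pass using a 2048-point
linear-interpolation table for θ∞; its agreement with the plain
numpy/scipy reference implementation is itself under test.

Subsets follow the recording protocol: traces grouped either by stimulus
protocol tag, or — after sorting by mean sub-threshold voltage —
accumulated until each subset holds at least 120 spikes (a trailing
under-filled subset merges into its predecessor).  Cross-validation
applies frozen parameters to held-out subsets and reports Γ, false-alarm
percentage and EV per subset.  A fixed-τ sweep re-optimizes the five
curve parameters at each τ on a grid, profiling Γ and EV against τ.

## Synthetic ground truth

Because the in vivo recordings are not public, validation uses simulated
neurons whose threshold dynamics are known exactly.  The neuron is an
exponential integrate-and-fire cell,

    τ_m dV/dt = (E_L − V) + Δ_T exp((V − θ)/Δ_T) + R·I(t),

with τ_m = 5 ms, E_L = −70 mV, R = 100 MΩ, reset to −70 mV, 0.8 ms
refractory, simulated by explicit Euler at 42 kHz, with θ evolving by the
threshold ODE above.  Spikes are registered at a detection ceiling
(0 mV); a stylized 0.3 ms triangular upstroke to +10 mV is superimposed
on the output trace so that peak- and onset-detection code paths run on
simulated data, and the hidden ground-truth threshold integrates the
reset-held voltage during the waveform and refractory, never the cosmetic
upstroke.  The injected current is an Ornstein–Uhlenbeck process (exact
discretization; mean 40 pA, SD 120 pA, correlation time 3 ms) plus a slow
OU envelope (SD 150 pA, correlation time 50 ms) standing in for the
100 ms sound-evoked depolarizations of the recordings.  An optional
hidden per-sample jitter of the spiking criterion is available to emulate
intrinsic unpredictability; the validation scenarios leave it off so that
a perfect prediction is attainable in principle.

**Why the validation scenarios use sharp initiation (Δ_T = 0).**  An
84 µs coincidence window constrains the threshold curve only through the
voltage the trace traverses within 84 µs of each spike.  With shallow
single-compartment initiation (Δ_T ≈ 1 mV) the upstroke traverses tens of
mV inside that window, so any curve crossing anywhere in that corridor
predicts every spike perfectly: the fit is structurally under-determined,
and profile analyses over (τ_θ, offset) come out exactly flat.  Two
degenerate families were identified this way: curves trading offset
against τ_θ along the pre-spike approach, and a "velocity detector"
(τ_θ ≈ dt, curve parallel to and just above the diagonal) that triggers
on the spike's own upstroke rather than predicting it.  Real somatic
onsets are kink-like — far sharper than single-compartment model
initiation, a point the source literature makes explicitly — and with
kink initiation the crossing happens at the speed of the sub-threshold
drive, shrinking the corridor to a fraction of a millivolt and making
τ_θ, the knee and the slopes identifiable.  The validation neurons
therefore use the Δ_T → 0 limit, and before fitting, each waveform +
refractory span of the simulated trace is excised to the reset potential
(`excise_spikes_to_reset`) — exactly the input the generative threshold
integrated, so the fitted model and the ground truth see the same drive.

**Scenario ground truths.**  Curves are chosen above the diagonal
θ∞(V) > V (as fitted curves in the source data are: spiking requires
depolarizing faster than the threshold adapts, which is what produces
measured-threshold distributions several mV wide, overlapping the
sub-threshold voltage distribution): constant (α = β = 0, θ = −55 mV,
identification of τ_θ and V_i is undefined here by construction); 
rectified (α = 0, β = 1, V_i = −59, θ₀ = −57, k_a = 3, τ_θ = 3 ms);
linear (α = β = 1, θ∞ = V + 8, τ_θ = 5 ms; V_i is unidentifiable since
only θ₀ − αV_i enters an affine curve); fast rectified (τ_θ = 0.3 ms,
θ₀ = −59, 0.5 ms input correlation time).  A current-grid suite varies
the fast-component mean over 20–200 pA and SD over 50–400 pA (rectified
truth), screening out cells with fewer than 20 spikes or rates at or
above 200 Hz.  Firing rates land in the tens of Hz.

The constant bias permitted when comparing recovered and true curves
absorbs the spike-initiation offset: with Δ_T > 0, spikes start above the
nominal threshold because the sodium activation opens gradually, and the
fitted curve shifts up by the corresponding amount.

## Effective signal

ES(t) = V(t) − θ(t); the neuron fires when the ES crosses 0 mV, so
voltage dynamics with an adaptive threshold are equivalent to ES dynamics
with a fixed threshold.  Because θ tracks slow voltage components,
adaptation acts as a one-pole high-pass filter: for small sinusoids in
the linear regime above the knee with β = 1, the ES/V amplitude ratio is
ωτ_θ/√(1+ω²τ_θ²) (verified within 5% over two decades of frequency).
Summary statistics (σ and autocorrelation half-height width of V and ES)
are computed on spike-excised data: 1 ms windows from each onset are
removed, and the mean-subtracted, biased-normalized autocorrelation
accumulates lagged products only over index pairs both outside excisions
(implemented by zero-filling, which contributes exactly zero to every
product).  The HHW is twice the first downward 0.5-crossing of the
normalized autocorrelation, located by linear interpolation; for
white-noise input HHW/(2 ln 2) estimates the membrane time constant.
Alpha-function PSP traces demonstrate the consequence for synaptic
integration: the slow exponential decay is filtered out of the ES, so the
effective PSP is briefer than the voltage PSP while its peak is barely
reduced — the integration window shortens toward τ_θ.

## Problem sizes

Validation fits use single 20 s traces at 42 kHz (about 10⁶ samples,
several hundred spikes) with a 2000-evaluation CMA-ES budget; scenario
suites run 10 seeds per scenario, and the current grid 3×3 cells.  These
sizes make desk-scale replication of every analysis possible in minutes
while leaving the recovered parameters stable across seeds.

## Known limitations

- The scalar knee voltage V_i is the least precise of the recovered
  parameters: V_i, k_a and θ₀ compensate within families of nearly
  identical softplus curves, and the knee sits at the lower edge of the
  onset-voltage band that pins the curve, so single-trace (20 s) fits
  localize V_i only to about ±2.5 mV even when the curve itself is
  recovered to a fraction of a millivolt.  The curve, not the knee
  scalar, is the robust deliverable of a fit.

- The synthetic neurons are single-compartment; nothing here validates
  against multicompartment initiation, channel noise, or conductance
  (rather than current) drive.
- The measured-onset pipeline assumes spikes with clear peaks (≥10 mV
  prominence); bursting with strongly degraded spike heights would need a
  different peak gate.
- Identification of τ_θ requires input with power both slower and faster
  than τ_θ and a threshold operating above the diagonal; data violating
  these conditions (e.g. tonic near-diagonal firing) yield flat Γ(τ)
  profiles, which the fixed-τ sweep makes visible.
- With shallow spike initiation in the *data* (not just the model), the
  coincidence objective at δ = 84 µs is under-determined, as described
  above; fits to such data should be read as predictive models, not as
  parameter measurements.
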