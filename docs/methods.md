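# Methods

This note documents the model implemented by `dendromux`, the choices made
where the design was genuinely open, and what the synthetic inputs do and do
not emulate.

## Scope of the abstraction

The package implements a *dendritic abstraction*, not a multicompartment
biophysical neuron.  Each branch is a lumped subunit with three stages —
location-dependent propagation, linear summation, dynamic thresholding — and
the only differential equations integrated are the somatic Hodgkin–Huxley
system.  Distributed active channels, backpropagating action potentials,
explicit dendritic spikes and inhibitory inputs are outside the abstraction:
the first appear only through the fitted propagation and thresholding
parameters, the second and third only through the artifact-filtering rule of
the IO pipeline, and inhibition not at all.

## Units and scaling

Voltages are millivolts internally; time is milliseconds; distances are
micrometres.  The unit-interval feature scaling maps −70 mV → 0 and
40 mV → 1 and is applied only at the IO-quantification and thresholding
boundaries.  The map never clips: dendritic values above 40 mV map above 1,
and whether to clip is the caller's decision.  (At this scaling a normalized
0.975 corresponds to 37.25 mV; the scaling definition is authoritative
wherever rounded mV equivalents would disagree.)

## Synaptic inputs

Receptor kinetics are peak-normalized double exponentials.  AMPA: 0.5 nS
peak, 0.2/2 ms rise/decay, 0 mV reversal.  NMDA: 0.16 nS, 2/86 ms, −5 mV,
multiplied by the magnesium unblock factor `1/(1 + [Mg]·e^(−0.062V)/3.57)`
at [Mg] = 1 mM.  The normalization constant is computed analytically from
the closed-form peak time `t* = (τ₁τ₂/(τ₂−τ₁))·ln(τ₂/τ₁)`, so the waveform
maximum equals the stated peak conductance exactly.  Equal rise and decay
constants (the alpha-function limit) are rejected rather than special-cased.

Spine-head voltage traces are synthesized directly as a rest-plus-double-
exponential template rather than derived from a conductance-injection
membrane model.  The template is calibrated to two summary statistics: a
14.81 mV single-event peak above the −70 mV rest and a 2.75 ms full width at
half maximum.  One FWHM constraint cannot pin down two time constants, so
the rise:decay ratio is fixed at 1:10 (the AMPA kinetics ratio) and the FWHM
sets the overall time scale; because the waveform scales linearly in time,
the calibration is a single division (resulting constants ≈ 0.274/2.74 ms).
Events superpose linearly at the spine head — no saturation toward the
reversal potential — and Gaussian voltage noise (default SD 0.2 mV) is added
to the template, not to the conductance.  This reproduces the two published
waveform statistics but not NMDA voltage-dependence of the spine waveform,
spine-neck nonlinearities, or activity-dependent amplitude variability;
tests passing on these inputs therefore validate the pipeline's arithmetic
and statistics, not spine biophysics.

Activation trains are homogeneous Poisson processes (exponential
inter-arrival times, default mean 20 ms, no refractory floor).  Stimulation
protocols place synapses uniformly inside fractional windows of the branch
length measured from the thresholding point: three segregated windows
(0.01d–d, 0.01d–0.5d, 0.5d–d) and four clustered quarters, crossed with
synapse counts {3, 5, 7} — 21 conditions.  The default run allocation is 10
runs for the whole-branch segregated window and 5 for each of the other six
(40 per branch); an alternative reading that applies this allocation per
synapse count is exposed as `run_allocation("per_count")`.

## Cable reduction and propagation

A branch is an ordered distal-to-proximal chain of cylindrical sections with
R_m = 10 000 Ω·cm², R_a = 100 Ω·cm, C_m = 1 µF/cm² by default.  The
reduction sums per-section contributions: `λ = Σ √(R_m d/4R_a)` (µm) and
`τ = Σ R_m C_m` (ms).  The per-section summation is deliberate and follows
the source convention for this abstraction even though it departs from
classical uniform-cable theory, where τ would not grow with the section
count; τ here is simply a per-branch scale that the fitted constant β
multiplies, so the departure is absorbed in the fit.

Propagation over distance x applies gain `α·e^(−x/λ)` and delay
`β·τ·x/(2π)`.  β is treated as a dimensionless fitted per-branch constant
that absorbs the µm→ms unit conversion, since the delay term mixes units and
only the fitted product is observable.  The delay is implemented as an
integer-sample shift (nearest sample at the 0.05 ms step) rather than
interpolation, which makes runs bit-reproducible; delays are therefore
quantized to ±25 µs.  Fitting uses peak statistics exactly as the
measurement procedure defines them: α from a log-linear least-squares fit of
peak-decay ratios with λ fixed by the cable reduction, β as the
through-origin least-squares slope of peak-time lags against τx/(2π).

## Dynamic thresholding

The branch nonlinearity is `g = a + bX₁ + cX₂ + dX₁X₂` followed by the
piecewise rule `f = g` if `g ≤ θ`, else `f = V_max`.  X₂ is the number of
synapses configured as active on the branch for the run — a static
per-simulation covariate matching how the regression variable was
constructed — not an instantaneous event count.  `f` is applied pointwise in
time to the normalized summation X₁(t); the function itself is
time-independent and the pointwise application is the minimal reading of
that property.

The shipped registry (`data/threshold_registry.yaml`) carries the tabulated
apical rows — primary (−0.023, 7.900, 0.007, −0.865, θ = 0.150,
V_max = 0.975), secondary (0.011, 1.357, 0.004, −0.115, θ = 0.200, 0.830),
tertiary (0.017, 1.395, −0.001, −0.107, θ = 0.270, 0.850) — and three basal
rows whose θ is not tabulated anywhere; those rows load with `theta = None`
and refuse to run the piecewise transform until a value is supplied or
estimated.  The primary row additionally carries a forced-spike rule
(`X₂ > 8` and `X₁ > 0.25` ⇒ `f = V_max`) stored as data on that row only: at
high synapse counts the fitted plane dips back below θ in a region that
empirically always spikes.

Two threshold conventions coexist and are deliberately not merged: the
registry θ values used by the piecewise rule (0.150/0.200/0.270) and the
empirical minimum suprathreshold `V_expected` (0.035/0.115/0.245 in the
apical branches), which `estimate_theta` computes from data (overall or
per synapse count).  Which one a user wants depends on whether they are
applying the tabulated function or re-deriving it.

## Somatic spiking

The soma follows a Hodgkin–Huxley system with Na⁺ (m³h), delayed-rectifier
K⁺ (n⁴), Ca²⁺ (s²r) and leak currents; conductances 120/36/7/0.1 mS/cm²,
reversals 45/−75/90/−70 mV, C = 1 µF/cm².  The drive current is 10 µA/cm²
per unit of summed normalized branch output, clipped below at zero.  The
rate expressions with removable singularities (α_m at −45 mV, α_n at −60 mV,
α_s at −27 mV) are evaluated by their analytic series limit rather than an
ε-offset, which removes a tunable fudge factor.

Integration is fixed-step classical Runge–Kutta at 0.05 ms — the integration
scheme is a package decision, chosen for reproducibility, with an adaptive
high-accuracy integration of the same equations used as an independent
cross-check in tests (agreement within one spike over 500 ms at unit drive).
The drive is held at its left-sample value across each step because it is a
sampled signal, not a closed form.  Initial conditions are V = −70 mV with
gates at their steady states z∞(−70); the system's actual resting point is
≈ −71.6 mV and is reached within tens of ms.  Spike detection — upward
crossings of 0 mV separated by at least 2 ms — is a package convention, as
no numerical spike definition accompanies the model.

## Multiplexer semantics

Simulation proceeds leaf to root.  A branch's own synaptic drive produces
X₁(t), then `f` with that branch's X₂.  A child's `f` output is converted to
electrotonic mV, propagated through the *parent's* cable (the parent's α, β
and full physical length — the child enters at the parent's distal end), and
summed with the parent's own `f` output without re-thresholding: the parent
acts as a multiplexer line.  Consequently a child output of, say, 0.18 that
exceeds the parent's θ = 0.15 must not be converted into a parent spike;
tests assert the soma drive is invariant to perturbations of the parent's
threshold row for child-only stimulation.  A branch with no active synapses
contributes `f = 0` rather than the regression intercept `g(0,0) = a`: the
intercept is a fit artifact and a silent branch is physically inactive (it
still relays its children's signals).

## IO quantification and artifact handling

Windows are bounded by interior strict local minima of the observed trace
(plateau ties resolve to the first sample of the plateau; both trace
endpoints also bound windows, an implementation necessity the windowing
definition leaves open).  Each window contributes the maxima of the observed
and expected traces.  Records whose observed peak lies strictly inside
(θ, 0.8) are removed as dendritic-spike/backpropagation artifacts —
"between" is read as an open interval, so boundary values survive.
Successful spikes are records at or above 0.8; subthreshold records at or
below θ.  Bin means use half-open bins of width 0.01 normalized units
(configurable; no width is prescribed anywhere).  Loess smoothing exists
only in the plotting layer and never enters quantitative output.

## Fitting and the closed loop

The surface fit is plain OLS on `{1, X₁, X₂, X₁X₂}` over subthreshold
records, with a 70/30 train/test split; stepwise term selection is not
performed since all four terms appear in every tabulated row.  θ and V_max
are not regression outputs: θ comes from the minimum suprathreshold
`V_expected`, V_max from the mean observed amplitude of successful spikes —
both estimator choices are package conventions, as the tabulated values'
derivation is not described.  A design spanning a single synapse count makes
c and d unidentifiable and is rejected.

The recovery harness closes the loop: simulate a toy-neuron branch under the
21-condition protocol machinery, quantify, fit, compare with the generating
registry row.  Noiseless, the loop is exact (coefficients recovered to
~1e−13) because subthreshold observed peaks lie on the generating surface by
construction — synaptic noise cancels since the expected and observed routes
share the spine traces.  With record-level measurement noise the recovery
error is governed by ordinary OLS statistics; at 500 records and noise
SD 0.01 the standard error of the intercept (≈0.0012–0.0019 depending on the
realized design) is comparable to 5 % of its magnitude (0.00115), so
recovering *every* coefficient within 5 % at that budget succeeds only for
favorable noise draws.  The harness defaults (3 runs of 1000 ms per synapse
count, stratified 500-record subsample) keep the full loop under ~10 s on
one CPU.

## Problem sizes and numerical tolerances

Default simulations run 1000 ms at 0.05 ms (20 001 samples).  The acceptance
script uses 500 ms for the cross-integrator check, 100 sweeps of 50 sites
for propagation recovery, 3 × 10⁶ evaluations for the thresholding range
sweep and 100 random traces for the windowing audit.  Peak-normalization and
round-trip identities are asserted at 1e−9–1e−12; noiseless fits at 1e−8.
Monte-Carlo assertions (Poisson train rate, placement uniformity,
coefficient coverage) use seeded generators with three-standard-error or
fixed-quantile bands.

## Known limitations

- The EPSP template is voltage-independent; NMDA kinetics affect only the
  conductance API, not the synthesized spine traces.
- Linear spine-head superposition can exceed physiological amplitudes under
  dense coincident activation (no saturation cap by default).
- The per-section λ and τ sums make the propagation constants
  geometry-dependent in a non-classical way; cross-morphology comparisons of
  β are not meaningful, only within-branch fits.
- Somatic spikes do not backpropagate; dendritic bursts exist only through
  the artifact filter, not as simulated events.
- `compare_spike_trains` uses a 200 ms window with a default 50 ms stride;
  the stride is a convention (no value is prescribed) and is configurable.
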