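# Methods

This note records the models, estimators and numerical choices behind
`seizurewaves`, in the order the pipeline applies them, together with the
design decisions that were genuinely open and the known limitations.

## Windowing and seizure intervals

Recordings carry seizure onset/offset annotations. Analysis uses 10 s
sliding windows stepped by 1 s (9 s overlap), beginning 60 s before onset
and ending at seizure termination. Each window is timestamped at its
*centre* and mapped to normalised seizure time (onset = 0, termination = 1);
the centre convention attributes a symmetric 10 s estimate to its midpoint.
Summary intervals on the normalised axis are Pre = [-0.5, 0), Early =
[0, 0.5), Middle = [0.25, 0.75) and Late = [0.5, 1.0]; Middle intentionally
overlaps Early and Late. When a recording provides less than 60 s of
pre-onset data (the desk-scale simulations provide 20 s), `make_windows`
accepts an explicit shorter `pre_duration`; windows never extend past the
termination annotation.

## Multitaper coherence and significance

Coherence between electrode pairs is estimated per window with discrete
prolate spheroidal (Slepian) tapers at time-bandwidth product TW = 20
(half-bandwidth 2 Hz for a 10 s window) and K = 2·TW - 1 = 39 tapers — one
less than the Shannon number. Tapers are weighted equally; eigenvalue
weighting changes nothing visible at TW = 20. Windows are demeaned before
tapering; no other detrending is applied because the 1 Hz lower band edge
already excludes slow trends. The frequency axis is kept to 25 Hz.

Significance uses the theoretical null for magnitude-squared coherence of
independent Gaussian signals averaged over K tapers, Beta(1, K-1), whose
upper-alpha quantile has the closed form `1 - alpha^(1/(K-1))`; at
alpha = 0.005 (the 99.5% level) and K = 39 the threshold is 0.130 on the
magnitude-squared scale. No multiple-comparison correction is applied to
the mask. Note the practical consequence: on truly independent noise the
expected significant fraction is 0.5% *per bin*, but neighbouring bins
within the 4 Hz smoothing span are strongly correlated, so calibration
tests must subsample bins at spacing > 2W before using binomial bands.

## Group delays from coherence phase

For each pair and window, the 1-13 Hz band is searched for a contiguous run
of significant bins spanning at least 3 Hz. If several qualify, the longest
run is used; ties go to the lowest frequency (deterministic, and the longer
run gives the phase fit more leverage). The coherence phase is unwrapped
across the run and regressed on frequency; the slope divided by 2·pi is the
group delay. The delay is *defined* only when the line beats a constant
model (F-test, p < 0.05). Positive delay means the second electrode lags
the reference, so the fitted spatial delay gradient points toward latest
arrival. Phase unwrapping before the fit matters: raw phase wraps at +-pi
for delays beyond roughly 40 ms in this band.

A caveat recorded deliberately: successive windows overlap by 9 s and
frequency bins within the multitaper bandwidth are dependent, so the
nominal F-test dof are optimistic. This mirrors the cited procedure; the
conservatism of the overall chain (three significance gates in series)
compensates in practice.

## Delay maps and the two spatial scales

Microscale: delays of every microelectrode against the central
microelectrode of the array (the electrode nearest the array centroid); the
reference itself enters the map with delay zero. Macroscale: the delay
between the microarray as a whole and each macroelectrode is the mean over
all defined microelectrode-to-macroelectrode pair delays; an entry with no
defined constituents is undefined. Only the 30 macroelectrodes closest to
the microarray are used (all nine virtual macroelectrodes in simulation).

## Plane-wave fits, speed and source direction

Defined delays D are regressed on 2D electrode positions,
`D = b0 + b1*X + b2*Y`, by iteratively reweighted least squares with Tukey
bisquare weights (tuning constant 4.685, MAD scale); plain least squares is
available and is used by the equivalence tests. A fit is *valid* only if
(i) at least 50% of the electrodes have defined delays and (ii) the plane
beats the constant model on the final weights (F-test with 2 numerator dof,
p < 0.05). For valid fits the wave speed is `1/sqrt(b1^2 + b2^2)` — the
delays are in seconds and positions in mm, so no 2·pi enters — and the
source direction is `atan2(b2, b1)`, the four-quadrant angle of the delay
gradient, pointing toward the largest delays. Invalid fits report no speed
or direction anywhere downstream: every reported statistic traces back
through a defined delay and a valid fit.

Direction consistency of a set of source directions is the phase-locking
value, the modulus of the mean unit phasor: 1 for perfectly repeatable wave
directions, ~`sqrt(pi)/(2*sqrt(N))` for N uniformly random directions.
Interval summaries report, per interval, the number of valid waves, the
direction consistency, the mean speed, and 95% percentile-bootstrap
confidence intervals from 1,000 resamples. Group comparisons pool the
Early/Middle/Late per-run values into one seizure group (sizes n versus 3n)
and use a two-sided two-sample t-test, reported uncorrected — this mirrors
the published bookkeeping even though Middle overlaps its neighbours.

Coherence-versus-distance regressions are ordinary least squares of
band-averaged (1-13 Hz) coherence on pair distance, summarised by the slope
and by the fitted values at the minimum and maximum *observed* distances
("left" and "right" intercepts). Evaluating at the observed extremes rather
than zero avoids extrapolating micro-to-macro pairs to meaningless zero
separation. Distances come from electrode positions (Euclidean) unless a
precomputed (e.g. geodesic) distance matrix is attached to the layout;
geodesic distances are always an input, never computed here.

## The cortical field model

The simulator extends a two-population mean-field cortical model of the
Steyn-Ross family. Per grid cell the fast subsystem integrates: mean soma
voltages V_e, V_i with conductance-like reversal weighting of synaptic
input; four second-order critically-damped synaptic flux filters (rates
gamma_e = 170/s, gamma_i = 50/s); and two damped wave equations carrying
long-range excitatory flux at axonal speed v = 280 cm/s with inverse range
Lambda = 4/cm. Inhibitory populations couple diffusively to neighbours
(gap junctions, D_ii), excitatory populations weakly (D_ee = D_ii/100 at
baseline). Parameter values follow the published sets of this model family
(Q_e^max = 30/s, Q_i^max = 60/s, theta = -58.5 mV, sigma_e = 3 mV,
sigma_i = 5 mV, rho_e = 1.00e-3 mV s, rho_i = -1.05e-3 mV s, N^alpha = 2000,
N^beta_e = 800, N^beta_i = 600, V rest -64 mV, reversal 0 / -70 mV), with
the seizure-specific overrides: membrane time constants 0.02 s, axonal
speed 280 cm/s, subcortical noise scale factor 2.

Three modifications tailor the model to seizure dynamics:

1. **No-flux boundaries**, implemented with mirrored ghost cells in every
   Laplacian (this also makes the potassium diffusion exactly
   mass-conserving on the discrete grid).
2. **Depolarization block.** The sigmoidal activation is multiplied by a
   one-sided Gaussian roll-off starting at -40 mV with 10 mV width, so the
   firing rate is maximal a little above threshold and approaches zero as
   the voltage exceeds -20 mV. The onset/width parameterisation is exposed
   (`block_onset`, `block_width`); the block centre itself is not fitted to
   anything — it shapes the high-voltage tail only.
3. **Slow extracellular-potassium subsystem.** Per cell, the unitless
   potassium proportion K obeys

       dK/dt = -delta*K + C1 * max(a - a0, 0) + C2 * lap(K)

   with decay delta = 0.1/s, gain C1 = 0.15, diffusion C2 = 1 cm^2/s, and
   activity `a = Q_e/Q_e^max + Q_i/Q_i^max`. The resting-activity floor
   a0 = 0.25 makes K measure the *ictal excess* of potassium: baseline
   firing is absorbed by glial uptake, so a quiescent sheet holds K = 0 and
   the potassium landscape is entirely seizure-generated. K relaxes the
   slow coupling fields toward clipped linear targets,

       tau_D * dD_ii/dt = max(D_base*(1 - g_D*K), D_floor) - D_ii
       tau_V * dV_b/dt  = min(g_V*K, dV_max) - V_b        (b = e, i)

   with tau_D = 4 s and tau_V = 25 s. The gains and clips
   (g_D = 2.5/unit K with floor 0.2 cm^2; g_V = 15 mV/unit K with ceiling
   6 mV) were calibrated once, jointly, to reproduce the qualitative ictal
   staging — quiet sheet, nucleation of a static mosaic at the source,
   spatially local colliding waves, then source-locked travelling waves —
   and then frozen. The steep, saturating form matters mechanically: once
   the recruited territory's K exceeds ~0.3, both slow fields sit at their
   clips *uniformly*, erasing the patterned excitability landscape laid
   down during recruitment; with gap junctions closed the Turing mosaic
   cannot persist, the bulk becomes a uniform deeply-oscillatory medium,
   and the forced source patch is the only faster pacemaker left — its
   target waves are what the virtual array records late in seizure.

The seizure source raises the excitatory resting-voltage offset to three
times the model family's reference offset (3 x 1.5 mV = 4.5 mV), over a
single cell in the headline configuration and a 3x3-cell patch at desk
scale (`source_radius_cells`). Scenarios: `fixed_source` holds it at one location for the
active segment; `random_source` redraws the location uniformly every 10 s;
`expanding_wavefront` applies the elevation on a distorted ring expanding
around the recorded territory (the domain centre) at ~1 mm/s: per-angular-
sector radial speeds are lognormal (sd 0.5) and are renewed every 4 s, so
the most advanced, most strongly igniting stretch of the front moves around
the ring over time while the electrodes sit in the seizing region behind
it; `quiescent` applies nothing. After deactivation the source cells simply rejoin the
potassium-elevated surround (their K-driven offset is whatever the local K
dictates).

Virtual electrodes sample the excitatory firing-rate field at 500 Hz: a
3x3 microarray of single cells at the domain centre and nine 12-cell
(3x4) macro patches — 108 mm^2 each at the headline 3 mm cell size — in a
ring around it.

## Numerics

Stochastic forward Euler at dt = 0.4 ms for the local terms; the
long-range flux wave equation uses a symplectic drift step followed by an
implicitly-damped kick, which is stable for omega_max*dt <= 2 instead of
the much tighter explicit-Euler bound (the highest spatial mode at 3 mm
cells and 280 cm/s conduction is omega_max ~ 2.9e3 rad/s, marginally
unstable under plain Euler at this dt once noise seeds it). Both bounds,
and the voltage-diffusion bound, are checked before a run and reject bad
configurations up front. The slow fields advance on a 10 ms subclock
(they change on 4-25 s time scales; the subclock stays inside the
potassium-diffusion stability bound). Subcortical flux noise is white
(variance scaled by 1/dt so its spectral density is step-size independent),
clipped at zero flux, with amplitude
`noise_sf * noise_base * sqrt(phi_sc/dt)`.

A fused numba kernel implements the fast step; a vectorised numpy
implementation of the identical update is kept alongside and agrees to
~1e-13 over short runs (the test suite checks this). Fixed seed gives
bit-identical recordings.

## Study conditions and the desk-scale configuration

The headline configuration is a 100x100 grid over 300 mm x 300 mm
(~9 mm^2 of cortex per cell), 180 s protocol with the source inactive /
active / inactive for 40/100/40 s, source at (75, 75) mm, ten noise seeds.
The desk-scale configuration used by the tests and the acceptance script
scales this to a 60x60 grid over 180 mm, 20/50/20 s, five seeds, source at
(45, 45) mm; its source patch (3x3 cells) keeps the footprint-to-domain
ratio of a compact cortical source.

A desk-scale limitation worth stating plainly: in the reduced domain the
territory recruited by the expanding wavefront settles into a single
spatially coherent oscillation whose direction at the central array is
stable within a run, so the wavefront scenario's direction consistency
stays high (~0.9) instead of dropping toward the headline contrast. The
interior mode is a long-range collective effect; at 180 mm the whole
recruited disc lies within one coherence domain, and neither stronger front
distortion, temporal renewal of the distortion, altered forcing, nor a
driven (subthreshold) interior broke its dominance. The fixed-versus-random
source contrast, which relies on the location of the dominant pacemaker
rather than on decoherence of a distributed one, is reproduced at desk
scale.

## What the synthetic data do and do not emulate

The kinematic generator produces exact plane waves: a shared band-limited
stochastic waveform (random-phase components spread over ~12 Hz) delayed
per channel by the position projection along the propagation direction,
plus independent Gaussian noise. A *pure* sinusoid would be useless here —
its cross-spectral phase is constant in frequency, so the group delay
(phase slope) of a delayed tone is zero — hence the broadband construction.
It validates geometry, delay, speed and direction recovery end to end.

The field model emulates the mechanistic claims: ictal staging, multiscale
coherence growth, travelling waves with direction consistency contrasts
between source scenarios, and the interventions (no potassium diffusion, or
no gap-junction closure, abolish the travelling-wave stage). It does not
emulate: folded cortical geometry (flat sheet, Euclidean ~ geodesic),
referencing artefacts of clinical recordings, high-frequency (>25 Hz)
onset rhythms (excluded by design), single-unit activity, or
patient-to-patient parameter variability. Passing tests therefore show the
*pipeline* behaves correctly and the *model* reproduces the published
simulation-level results at desk scale; they are not evidence about any
particular patient recording.

Known limitations: seizure termination in the calibrated regime is driven
by source deactivation plus potassium decay and is gradual rather than
abrupt; bootstrap CIs treat overlapping windows as independent (as in the
source procedure); and the delay estimator's F-test dof ignore bin and
window correlation (see above). Only plane waves are modelled or detected —
spirals and more complex patterns are out of scope.
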