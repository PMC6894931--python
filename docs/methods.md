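# Methods

This note documents the models, defaults and design choices behind the
package, in the spirit of a simulator's methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Session-plan combinatorics

A session plan is an ordered list of `(n_new, n_old)` pairs.  The first
session records `n` cells and probes all `n(n-1)` ordered pairs; a
clean-to-extend session adds `2·n_new·n_old + n_new(n_new-1)` new pairs,
because each new↔old pair is probed in both directions and old↔old pairs
were already probed while the maintained cells were co-recorded.  The plan
tracker materialises a directed boolean mask over all cells and verifies
the closed form against the mask's popcount on every call.

The maintained cells default to the first `n_old` cells of the most recent
non-empty active set.  This guarantees the maintained set was pairwise
co-recorded, which the closed form requires.  An explicit `keep` list can
name any other maintained set (e.g. keeping cells from several earlier
sessions); in that case the mask popcount is authoritative and may exceed
the closed form when previously never co-recorded cells are brought
together.

Success rate is the mean recorded-cluster size over the available pipette
count, reported as an integer percent (round half up) because that is how
rig performance is conventionally quoted; the raw ratio is also available.

### Yield model

`simulate_yield` is a deliberately coarse Monte-Carlo model: pipettes
attempt patches sequentially, each succeeding with probability `p_patch`,
and every attempt endangers each already-established recording with
probability `p_loss_per_patch` (mechanical interference grows with
activity).  With cleaning enabled, a failed pipette retries on a fresh
neighbouring cell up to `max_retries` times.  Extension rounds maintain
`n_keep` cells (default half the pipettes) and re-patch the rest, with
losses attributed to maintained cells first since the model does not track
cell identity.  The model is calibrated qualitatively — cleaning must
dominate no-cleaning in cluster size — not to any particular rig's numbers,
which depend on unmodelled tissue and operator factors.

## Rig geometry

Coordinates are right-handed, z up, micrometres, with the microscope/stage
frame canonical.  Registration uses the Kabsch algorithm (SVD of the
centred cross-covariance with determinant sign correction), requiring at
least three non-collinear correspondences; reflections are never returned.
A pipette's axis is defined by its azimuth (bearing of forward tip motion)
and approach angle above horizontal, default 27° — steep enough to reach
into the slice over the recording-well wall, shallow enough to retain
x-range.  Approach paths move in free space at constant height and descend
along the axis so the tip never shears the tissue laterally.  Reachability
reduces to a standoff inequality: the horizontal distance from the wall to
the target must be at least `(wall_top − target_z)/tan(approach)`.  The
collision model is tip-point distance only; shank cones are out of scope.
Staging height defaults to 200 µm above the slice surface.

## Virtual pneumatics

Channel levels: LOW +20 mbar (idle outflow), HIGH +70 mbar (slice
penetration), PATCH operator-variable (sealing suction needs manual
finesse and is modelled as a scripted parameter), ATMOSPHERE 0 mbar
(established recordings), CLEAN alternating −350 mbar suction and +1000
mbar (1 bar) expulsion.  Each pipette's three-valve tree is modelled as a
configuration table — root valve selects {LOW, HIGH/PATCH} versus
{ATMOSPHERE, CLEAN}, the branch valves pick within — giving a bijection
between the four routable sources and the canonical valve states (HIGH and
PATCH share one regulator output).

The cleaning schedule is fixed: five 1 s suction / 1 s expulsion cycles in
the detergent well (cycles start with suction), a 10 s expulsion still in
the detergent well, and a final 10 s expulsion at the recording-well rim —
12 steps, 30 s of active pressure.  Movement legs are straight lines at a
constant configurable speed with no acceleration model, so a realistic
~28 s of travel brings the whole round to about one minute.  The simulation
clock is discrete-event with float-second timestamps, non-decreasing per
pipette; pipettes holding cells are never touched by a cleaning round.

Detergent carry-over is a one-line mass balance: percent LAS =
`100·v_adherent·f_alconox·f_LAS/(v_bath + v_adherent)`.  With the default
assumptions (≤0.2 µl adhering, 1 ml bath, 2% Alconox of which 20% LAS) the
bath concentration is ~8×10⁻⁵ %, an order of magnitude below the 0.001%
receptor-interference level.  Inverting the same formula puts the critical
adherent volume near 2.5 µl; descriptions of this safety margin elsewhere
sometimes quote a tenfold larger critical volume, which the formula under
the same stated assumptions does not reproduce — the package reports the
mass-balance value.

## Synthetic data generator

The generator emulates the connectivity-screening recording conditions:
20 kHz sampling, current-clamp channels held near −60 mV, one stimulation
slot per cell of 4 suprathreshold pulses at 20 Hz, 30–50 sweeps, 250 ms
between slots.  A pulse fires iff its charge (amplitude × width) reaches
the cell's rheobase charge (default 2 nA·ms).  All randomness derives from
one root seed through numpy `SeedSequence` child streams spawned in a fixed
order (adjacency, edge parameters, positions, trial jitter, noise), so
sub-results are independently reproducible.

**Action potentials** are a parametric piecewise waveform: an exponential
foot whose dV/dt grows in proportion to the voltage above a floor and
crosses 10 mV/ms exactly at the nominal threshold, an exponential upstroke
to the peak (τ ≈ 0.2 ms), exponential repolarisation to an
after-hyperpolarisation (τ ≈ 0.5 ms) and slow recovery.  Ground truth
(threshold sample by the slope rule, half-width at threshold + half
amplitude) is bookkept on the clean waveform with the same central
difference convention the analysis uses, so recovery can be asserted to
within one sampling interval.

**PSPs** are difference-of-exponentials kernels `e^(−t/τ_d) − e^(−t/τ_r)`
normalised to unit peak (defaults τ_r = 2 ms, τ_d = 20 ms, peak at
`ln(τ_d/τ_r)·τ_rτ_d/(τ_d−τ_r)` ≈ 5.1 ms).  Trial-to-trial variability is a
multiplicative log-normal scale with unit mean and configurable CV
(default 0.3); release failures are available but off by default.  Edge
amplitudes are truncated normals (resampled below the floor rather than
clipped, to avoid an unphysical atom at the minimum), latencies are
normals clipped to a monosynaptic 0.8–3.5 ms.

**Noise** is white Gaussian (0.2 mV current clamp, 5 pA voltage clamp)
band-limited at 6 kHz like the acquisition chain.  The low-pass is a
symmetric 81-tap FIR applied zero-phase, in single precision for the big
sweep grids; it is applied to the noise component so event timing in the
deterministic signal component stays exact.  Band-limiting reduces the
sample SD of the 0.2 mV noise to ≈0.155 mV; detection thresholds are always
taken from measured baseline SD, not from the generator parameter.

**Voltage-clamp test pulses** follow the single-compartment response
`I(t) = dV/Ra·e^(−t/τ) + dV/(Ra+Rin)(1−e^(−t/τ))`, τ = Cm·Ra∥Rin, with
baseline segments before and after the 200 ms, 10 mV step.

The generator does not model conductance-based membrane dynamics, network
reverberation, short-term plasticity, electrode drift or line noise.
Passing tests on this data therefore demonstrate the correctness of the
analysis arithmetic and its statistical calibration under stationary
Gaussian noise — not robustness to every artefact of real recordings.

## Trace analysis

Resting potential: mean of the first 100 ms.  Access resistance from the
current extremum in the first 10 ms after pulse onset, input resistance
from the mean over the last 20% of the pulse, series-corrected
(`Rin = dV/(I_ss−I_base) − Ra`); an uncorrected variant is a flag away.
Degenerate pulses are flagged rather than guessed at: a non-positive
steady-state deflection is non-physical, and an absent charging transient
makes Ra and Rin inseparable.  Spike detection: local maxima above 0 mV
preceded within 2 ms by dV/dt ≥ 20 mV/ms, 2 ms refractory.  AP threshold:
walking back from the rising flank's maximum-slope point, the first sample
of the contiguous run with dV/dt ≥ 10 mV/ms above the baseline slope
(baseline slope ≈ 0 for held cells).  Amplitude is peak − threshold by
construction; half-width uses sub-sample linear interpolation at
threshold + amplitude/2.  The stimulus chooser scans 0.5–4 nA in 0.5 nA
steps at 1 ms, escalating duration (1→2→3 ms) only when nothing fires, and
returns the lowest firing amplitude plus one step (the "second lowest"
firing amplitude on a contiguous grid), capped at 4 nA.  QC boundary
semantics are deliberate: resting potential strictly above −60 mV excludes,
access resistance strictly below 40 MΩ is required.

## Event detection and connection calling

The template-scaling detector fits `scale·template + offset` to the trace
at every offset by closed-form least squares; the detection criterion is
`scale / SE` with `SE = √(SSE/(N−1))`, N the template length — the
classical template-matching convention.  The implementation uses centred
sliding sums (numerically equivalent to per-offset regression to better
than 1e-9 relative) and caps perfect fits at a sentinel of 1e12.
Spontaneous events are one per contiguous above-threshold region of the
criterion (threshold 4, refractory 5 ms), with amplitude = scale for a
unit-peak template.  The default spontaneous template window is 25 ms
(rise plus roughly one decay constant): long enough to constrain the fit,
short enough that a neighbouring event rarely sits inside the residual
window and dilutes the criterion.

Evoked connections are called on sweep-averaged traces.  Amplitude is the
extremum of the baseline-subtracted average in a 0.5–15 ms window after
the *first* presynaptic spike (later pulses in the 20 Hz train are
reported but not used for the binary call, avoiding short-term-plasticity
confounds).  The baseline is the 50 ms before the spike.  A pair is
connected when three conditions hold: |amplitude| ≥ k_sd × baseline SD
(default k_sd = 3), the 10%-rise latency falls in the monosynaptic
0.5–5 ms window, and the template-scaling criterion in the response window
reaches 4.  The template conjunct exists because the window-extremum
statistic alone is poorly calibrated: the maximum of ~300 correlated noise
samples exceeds 3 baseline SDs roughly 15% of the time, whereas the
criterion normalises the fitted PSP scale by the full residual and stays
far below threshold on noise.  All three quantities are reported per call
for audit, and k_sd, the latency gate and the criterion threshold are
configurable.  The evoked template window is 30 ms so the fit never reaches
the next pulse's PSP 50 ms downstream.  Sign convention: EPSPs positive at
−60 mV holding; detection uses |amplitude| with the expected sign recorded.

## Statistics

Connection probability is found/tested over directed pairs.  Fisher's
exact test uses the common probability-mass ordering for the two-sided p
(delegated to scipy; the test suite checks it against exhaustive
hypergeometric enumeration).  The Wald interval for a difference of
proportions is the simple asymptotic form without continuity correction,
z from the standard-normal quantile at (1+level)/2 (1.6449 at 90%).
Equivalence reporting follows the CI–TOST duality: the mean relative
difference `100·(after−before)/before` with its t-based 90% CI is
equivalent at bounds ±b iff the CI lies inside [−b, +b]; unpaired
comparisons use the relative difference of group means with a delta-method
SE and Welch–Satterthwaite degrees of freedom.  Rank tests dispatch to
exact Mann–Whitney/Wilcoxon for small tie-free samples and the normal
approximation otherwise.  Repeated-measures ANOVA is a thin wrapper over
statsmodels' `AnovaRM`.

## Problem sizes and tolerances

The test suite exercises the pipeline at the sizes the workflow itself
uses: 8-cell clusters of 40 sweeps (the full screening configuration, 100
seeds for the adjacency-recovery check), 2 s spontaneous traces, 100-AP
feature sweeps, exhaustive Fisher tables with margins up to 15 and
1000-replicate coverage simulations.  Numerical tolerances are stated per
test: machine-precision (1e-9) for the registration and template-fit
algebra, one sampling interval for waveform features, 5%/2% for
access/input resistance on noiseless pulses, and sampling-statistics
bounds (3σ) for Monte-Carlo quantities.

## Known limitations

- The yield model ignores tissue heterogeneity, operator skill and time
  costs; it supports strategy comparisons, not absolute predictions.
- The connection caller assumes stationary baseline noise and a known PSP
  time scale; strongly depressing synapses, polysynaptic cascades and
  oscillating baselines are outside the synthetic model and untested.
- Valve routing is a logical model; pneumatic transients, tube compliance
  and microcontroller timing are not simulated.
- The registration model is rigid: it cannot absorb manipulator axis
  non-orthogonality or scale errors, which would appear as residual RMS.
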