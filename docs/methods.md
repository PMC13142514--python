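# Methods

## The model

`ca1ei` simulates the subthreshold membrane-potential dynamics of a single
hippocampal CA1 place cell during simulated treadmill running on a 200 cm
circular track. The cell is a single passive compartment

    τ_cell · dV/dt = −(V − E_leak) − I_syn · R_inp

with τ_cell = 20 ms and R_inp = 100 MΩ, receiving three rate-driven synaptic
conductances: excitatory AMPAR and NMDAR (E_rev = 0 mV) and inhibitory GABAR
(E_rev = −70 mV). Currents follow I_X = g_X·(V − E_X) with inward
(depolarizing) currents negative; the NMDAR current carries an additional
sigmoidal voltage-dependent factor 1/(1 + exp(−β·(V − V_half))) approximating
the Mg²⁺ block, which is the only nonlinearity in the model. Each conductance
integrates a weighted sum of presynaptic firing rates,

    dg_X/dt = −g_X/τ_X + g_unit,X · Σ_i w_i,X · r_i(t),

with τ_AMPAR = τ_GABAR = 5 ms and τ_NMDAR = 75 ms. Unitary conductances are
in µS so that g·V (mV) is a current in nA and I·R (MΩ) is a voltage in mV;
rates in Hz carry a 1e-3 factor to the ms time base.

There are no spikes, no voltage-gated channels besides the NMDAR gate, and
no plasticity: the scientific question is whether the *subthreshold*
signature of a place field — the slow ramp, the intracellular theta
oscillation and its phase precession, and the responses to perturbations of
inhibition and of holding potential — constrains the spatial tuning of
synaptic inhibition once NMDARs are present.

## Synthetic inputs

All inputs are generated, not recorded; the input-population module is the
study's synthetic-data generator and its defaults are the study conditions:

* **Trajectory** — constant 25 cm/s running (one 8 s lap per 200 cm), dt =
  0.5 ms. The speed is a design choice (nothing in the protocol fixes it);
  25 cm/s makes the 4 s phase-precession window span 100 cm and the 0.4 s
  measurement windows span 10 cm of track, which keeps the window
  semantics aligned between time and space.
* **LFP reference** — a 7 Hz phase clock; each trial draws a uniform random
  phase offset so that averaging across trials decouples theta phase from
  track position.
* **CA3 place cells** — 1000 cells, field centers equally spaced. Spatial
  tuning is a "floor Gaussian": a Gaussian of circular distance, shifted and
  rescaled to equal 1 at the center and exactly 0 at distance ≥ 30 cm
  (floor width 60 cm), peak rate 25 Hz, out-of-field rate 0 Hz. The exact
  in-field profile is under-determined by a floor-width statement alone; we
  use σ = floor_width/(3√2), which keeps the profile visibly Gaussian and
  reproduces the interneuron calibration figures below to ~1.5%. Each cell
  phase-precesses a full 360° across its field, crossing the population
  phase φ_CA3 at its center; rate modulation is exp(k·cos Δφ) with k = 0.7,
  normalized to [0, 1] and mixed with depth d_CA3 = 0.7 (modulation factor
  range [0.3, 1]).
* **Interneurons** — two subpopulations of 500 cells with floor-Gaussian
  spatial modulation (60 cm floor width), one positively and one negatively
  tuned, each calibrated to a 25 Hz spatial mean rate. The negative
  population is constrained to 0 Hz at its trough, which fixes its
  out-of-field baseline at 29.6 Hz. The positive population is
  under-determined by the mean alone; its peak-to-baseline ratio is a
  configuration constant (default 47.7/21.3, giving 20.9 → 46.9 Hz).
  Theta modulation is cosine-shaped with depth d_INH = 0.5 (factor range
  [0.5, 1]) at a preferred phase φ_INH shared by both subpopulations.

## Connectivity and the three inhibition schemes

AMPAR weights from CA3 are deterministic: 1 + ΔW·fg(distance between the
presynaptic field center and the CA1 field center), floor width 60 cm.
NMDAR weights are all 1 (all 0 in variants without NMDARs) and are *not*
spatially tuned; GABAR weights are all 1. The spatial shape of total
inhibition is set purely by which interneurons connect: each interneuron
connects independently with probability proportional to a floor-Gaussian
preference over its modulation center whose width equals the full track
(200 cm). *Uniform* = flat preference; *balanced* = positively tuned
interneurons preferred near the field and negatively tuned ones far from
it; *reciprocal* = the opposite. The expected connection count per
subpopulation is split so the mean summed drives of the two subpopulations
match (an even split here, since both are calibrated to 25 Hz). The total
expected count is a configuration constant (300); the absolute strength of
inhibition is carried by g_unit,GABAR. Each Bernoulli draw uses fixed
per-instance uniforms, so connectomes grow monotonically with the budget
and are exactly reproducible from the instance seed.

## Numerics

Conductances use exponential-Euler (exact decay, rate sum held constant
over the step); the voltage uses forward Euler with the updated
conductances, dt = 0.5 ms = 0.1·τ_min. The discretization was validated
against an adaptive high-accuracy reference integration (`solve_ivp`,
rtol 1e-10) on smooth theta-modulated drives: trajectories agree within
0.05 mV, and halving dt changes traces by < 0.1 mV.

The per-candidate cost of parameter search is dominated by the weighted CA3
rate sums, so the package evaluates them through a Bessel-function
expansion: exp(k·cos θ) = I₀(k) + 2·Σ_m I_m(k)·cos(mθ), truncated at m = 6
(relative truncation error < 1e-5 at k = 0.7). The per-cell phase argument
separates into a cell- and time-dependent part plus a global offset
(φ_CA3 − φ_trial), so a handful of complex harmonic time series, computed
once per trajectory, yield the drive for any candidate phase and modulation
depth in O(n_t). The fast path is cross-checked against the direct
per-neuron product of spatial tuning and temporal modulation in the test
suite (agreement to 1e-6 relative).

## Protocols and measurements

Simulations run 3 laps plus a 2 s run-out; the first lap is warm-up
(conductance transients die within ~5·τ_NMDAR ≈ 0.4 s) and is excluded
from analysis. Five trials per condition differ only in the LFP phase
offset; five network instances differ in the inhibitory connectome.

* **Control** — nothing applied.
* **Reduced inhibition** — every GABAR conductance scaled by 0.5 at every
  time step (conductance scaling is linear, so this is exact).
* **Depolarized** — a sustained extrinsic current, calibrated by bisection
  so the out-of-field voltage hits each target in a −61…−55 mV series
  (the calibration reuses cached conductances; only the voltage
  integration reruns).

Features: the ramp is the trial-averaged < 2 Hz low-pass voltage, averaged
within 0.4 s windows at the field peak (in) and at the diametrically
opposite position (out) — the out-window placement is a design choice, the
protocol states only "0.4 s windows". Theta amplitude is the Hilbert
envelope of the 4–10 Hz band-pass (4th-order Butterworth, forward-backward)
averaged the same way. Theta peaks are detected per trial on the band-passed
trace with a half-period minimum separation; each peak gets the LFP phase
and track position at its time. Out-of-field phase is the circular mean of
peaks > 60 cm from the field center. Precession extent is measured from the
phase-versus-position map (5 cm bins, circular mean per bin, greedy
nearest-cycle unwrapping) as unwrapped entry-minus-exit phase across the
4 s (100 cm) window centered on the field: an endpoint-difference estimator
(a regression estimator would be an alternative; endpoint difference on the
binned map matches how the map is constructed). Excitability is the
least-squares slope of ramp amplitude against out-of-field voltage across
the depolarization series including the control point.

## Optimization

Nine free parameters per variant: ΔW_AMPAR, the three unitary conductances,
the NMDAR gate's β and V_half, the two population preferred phases (φ_CA3,
φ_INH), and E_leak. E_leak is searched rather than recalibrated per
candidate: out-of-field Vm is itself a two-sided optimization objective
(target −63 mV), which makes the resting level a property the optimizer can
trade against other targets instead of a constraint satisfied by
construction. A bisection calibration of E_leak (and of the holding
current) is still provided and tested; it pins the resting voltage to
0.2 mV when a fixed-resting-potential model is wanted. The expected
inhibitory connection count is a configuration constant rather than a
search dimension — its effect on the mean inhibitory conductance is
degenerate with g_unit,GABAR. Variants without NMDARs pin g_unit,NMDAR = 0
(β and V_half become inert).

Objectives are tolerance-normalized squared errors, saturated at 25 (five
tolerances). The saturation is a robust-loss choice with a structural
reason: for variants without NMDARs the positive ramp-vs-holding-slope
target is unattainable, and an unbounded squared penalty on it would
dominate the total error and push the search to sacrifice attainable
targets (notably the ramp amplitude); saturating keeps every objective's
gradient intact near its target while letting hopeless objectives simply
plateau. Targets are the experimental values (resting Vm −63 mV ± 5; ramp 6 mV ± 2; out-of-field theta peak
phase 180° ± 20 in control and under reduced inhibition; and one-sided
"soft" targets penalizing only undershoot: in−out theta amplitude > 0.5 mV,
precession extent > 100°, ramp-vs-holding slope > 0.23 mV/mV, ΔVm > 1.5 mV
and Δtheta > 0.2 mV in- and out-of-field under reduced inhibition; soft
tolerances are the printed half-width where one exists, else 20% of the
target). The change of precession extent under reduced inhibition (target
< −25%) is held out: reported for every candidate, never part of the total
error. Errors are averaged across network instances.

The search is an elitist evolutionary loop: uniform initialization within
bounds, binary tournaments decided by Pareto (non-domination) rank with the
total error breaking ties, uniform crossover, Gaussian mutation annealed
from 15% to 0.5% of each parameter's range (angles wrap, others clip), 25%
elites by total error, 10% fresh random immigrants per generation, and
multiple restarts whose archives are pooled. The first restart's initial
population contains one deterministic warm start — the default candidate
with its leak reversal calibrated by bisection — and each later restart is
seeded with the pooled archive's per-objective champions plus the overall
leaders, so a lineage that alone satisfies a hard objective survives into
the fresh run. Pareto-rank selection is
load-bearing: a lineage that alone satisfies a hard objective (the
ramp-vs-holding slope, which requires recruiting the NMDAR nonlinearity)
stays on the first front and keeps breeding even while its summed error is
still high, instead of being culled by scalarized selection. On a 9-D
quadratic with known optimum it recovers the optimum within 1% of the range
at a 2000-evaluation budget. Desk-scale runs here use 1000–2000 evaluations
with 1 instance × 2 trials per candidate (the full study regime of 30,000 ×
5 instances is supported by the same code path). Because 2-trial
evaluations are noisy, the lowest-error candidate is partly selected *for*
favorable noise; the final model is therefore chosen by re-evaluating the
top ten candidates at the full 5-trial protocol and re-sorting
(winner's-curse correction), and reported measurements use calibrated
depolarization targets. Degenerate low-error families ("Marder groups") are
extracted by greedy clustering of the archive with a range-normalized
parameter distance.

## Criterion table

Twelve criteria mirror the experimental evaluation. "target ± tol" rows are
closed intervals; "> x ± y" rows are one-sided with the tolerance belonging
to the optimization softness, so the pass threshold is x − y (documented
choice; the alternative — pass at x — would double-count the tolerance).
Families of five models are judged pass at ≥ 4/5 members, fail at ≤ 1/5,
and reported verbatim in between.

## What the generator does and does not emulate

The synthetic inputs reproduce the *first-order* statistics that the
experimental targets constrain: spatial tuning curves, theta modulation
depths, phase precession of CA3 inputs, and interneuron mean rates. They do
not emulate spiking variability (inputs are rates, not spike trains),
running-speed variability, inhomogeneous field widths or peak rates across
cells, theta frequency drift, or experience-dependent changes. Passing
tests therefore show that the model equations and measurement pipeline
behave as specified under these idealized conditions — not that the model
captures every property of in vivo recordings.

## Known limitations

* The ramp-vs-holding slope target is the hardest objective: it requires
  recruiting the NMDAR nonlinearity within the stated −63…−55 mV holding
  range, and for the balanced configuration (total inhibition rising ~30%
  in-field) the satisfying parameter region is narrow. The warm start and
  champion reseeding exist precisely because plain restarts missed such
  regions at desk-scale budgets; fitted models near these regions can show
  very large in-field depolarizations under reduced inhibition (the
  one-sided objectives place no upper bound on ΔVm).

* Single compartment: all synapses see the same voltage; dendritic
  compartmentalization would spread NMDAR activation across a range of
  local voltages.
* The positive interneuron population's peak-to-baseline ratio is not
  derivable from the stated constraints and is exposed as configuration.
* At desk-scale search budgets the optimizer occasionally converges to a
  qualitatively different local optimum (e.g. a weak-precession regime);
  budgets of ~2000 evaluations with the annealed/immigrant search settings
  were reliable in our runs, and the archive always reports what was found.
* Reported features at reduced trial counts (2 trials during search) shift
  slightly when re-measured at 5 trials; final measurements always use the
  full trial count.
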