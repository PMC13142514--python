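# ca1ei — CA1 place cells, NMDARs, and the spatial tuning of inhibition

Hippocampal CA1 place cells depolarize at a specific track location (the
"place field"). Whether the *inhibitory* synaptic conductance they receive
is itself spatially tuned has been argued both ways from perturbation
experiments: extrinsic depolarization reveals extra excitability inside the
field (suggesting inhibition drops in-field), while optogenetic suppression
of interneurons depolarizes place cells uniformly (suggesting spatially
flat inhibition). `ca1ei` implements the modeling study that reconciles the
two: a single-compartment, rate-driven place-cell model in which
voltage-dependent NMDARs counterbalance the growth of GABAR driving force
with depolarization — so that *any* spatial profile of inhibition (uniform,
balanced, or reciprocal) reproduces the full battery of experimental
observations, while models without NMDARs succeed only with reciprocally
tuned inhibition for one experiment and fail the other.

It is intended for computational neuroscientists who want to rerun,
modify, or extend that analysis: every step — synthetic input generation,
conductance-based simulation, perturbation protocols, intracellular
feature extraction, and multi-objective model fitting — is an importable,
tested library function, with thin numbered drivers under `analysis/`.

## The model

Membrane voltage of a passive single compartment (τ_cell = 20 ms,
R_inp = 100 MΩ):

    τ_cell·dV/dt = −(V − E_leak) − (I_AMPAR + I_NMDAR + I_GABAR)·R_inp
    I_X = g_X·(V − E_X),   I_NMDAR scaled by 1/(1 + exp(−β(V − V_half)))
    dg_X/dt = −g_X/τ_X + g_unit,X · Σ_i w_i,X·r_i(t)

Inputs: 1000 CA3 place cells (60 cm floor-width Gaussian fields, 25 Hz
peak, full-cycle theta phase precession) and two 500-cell interneuron
populations (positively / negatively tuned, 25 Hz mean rate, theta-locked),
driving AMPAR/NMDAR and GABAR conductances on a 200 cm circular track with
a 7 Hz LFP-like reference. The spatial shape of total inhibition (uniform /
balanced / reciprocal) is set by scheme-dependent connection probabilities.
Perturbations mirror the experiments: a sustained calibrated depolarizing
current, and a 50% scaling of all GABAR conductances. See
`docs/methods.md` for the complete description.

## Worked example

`analysis/02_simulate_example.py` simulates one (un-optimized) uniform-
inhibition NMDAR model, calibrates its leak reversal and a holding current,
runs all three protocols and prints the extracted features:

```
calibrated e_leak = -68.20 mV for a -63 mV out-of-field Vm
holding current for -59 mV out-of-field: 60.9 pA
features:
  vm_out               -63.15
  ramp                   5.27
  theta_in               1.26
  theta_out              0.28
  dvm_out                1.53
  dtheta_out             0.33
  dprecession_pct      -57.26
  slope                 -0.06
  ...
```

Reading it: the cell rests at −63 mV out-of-field and ramps up ~5 mV inside
its field; its intracellular theta oscillation is larger in-field (1.26 vs
0.28 mV); halving inhibition depolarizes it by 1.5 mV out-of-field and
boosts out-of-field theta by 0.33 mV; phase precession collapses by 57%
under reduced inhibition. The negative ramp-vs-holding slope (−0.06 mV/mV)
is typical of an *unfitted* model — producing the experimentally observed
positive slope (> 0.23) is exactly what optimization of the NMDAR
parameters achieves.

The full pipeline:

```sh
python analysis/01_inputs_and_connectivity.py   # input calibration tables
python analysis/02_simulate_example.py          # example traces + features
python analysis/03_optimize_variants.py         # fit all six variants
python analysis/04_criterion_table.py           # criterion/verdict matrix
```

Outputs land under `results/`. The optimization driver takes
`--budget/--seed` flags; the default 2000-evaluation budget fits one
variant in a few minutes on one CPU (the full-scale 30,000 × 5-instance
regime uses the same code path).

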