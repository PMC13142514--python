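#!/usr/bin/env python
"""Build and summarize the synthetic input populations and connectivity.

Writes to results/inputs/:
  - interneuron_calibration.csv : baseline/extremum rates of the two
    interneuron subpopulations after the mean-25 Hz calibration
  - inhibitory_profiles.csv     : trial-averaged summed inhibitory spatial
    rate for the uniform / balanced / reciprocal schemes
  - ca3_drive_profile.csv       : summed CA3 spatial drive with and without
    the AMPAR place-field weighting

Prints the headline calibration numbers.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ca1ei.connectivity import (ampar_weight_profile,
                                sample_inhibitory_connections,
                                summed_inhibitory_rate)
from ca1ei.inputs import (Ca3Population, InterneuronPopulation,
                          calibrate_interneuron_rates)
from ca1ei.params import StudyConfig

OUT = Path("results/inputs")
OUT.mkdir(parents=True, exist_ok=True)

cfg = StudyConfig()

rows = []
for polarity in ("positive", "negative"):
    baseline, extremum = calibrate_interneuron_rates(
        polarity, cfg.inh_floor_width, cfg.track_length, cfg.inh_mean_rate,
        peak_to_baseline=cfg.pos_peak_to_baseline)
    rows.append({"polarity": polarity, "baseline_hz": round(baseline, 2),
                 "extremum_hz": round(extremum, 2)})
    print(f"{polarity:8s} interneurons: baseline {baseline:5.2f} Hz, "
          f"extremum {extremum:5.2f} Hz (spatial mean {cfg.inh_mean_rate} Hz)")
pd.DataFrame(rows).to_csv(OUT / "interneuron_calibration.csv", index=False)

pops = [InterneuronPopulation.calibrated(p, cfg) for p in ("positive", "negative")]
x = np.linspace(0.0, cfg.track_length, 401)
profiles = {"x_cm": x}
for scheme in ("uniform", "balanced", "reciprocal"):
    acc = np.zeros_like(x)
    n_seeds = 5
    for seed in range(n_seeds):
        conn = sample_inhibitory_connections(scheme, pops, cfg.field_center,
                                             cfg.n_inh_connections, seed,
                                             pref_floor_width=cfg.pref_floor_width)
        acc += summed_inhibitory_rate(conn, pops, x)
    profiles[scheme] = acc / n_seeds
    in_field = profiles[scheme][np.abs(x - cfg.field_center) < 10.0].mean()
    out_field = profiles[scheme][np.minimum(np.abs(x - cfg.field_center),
                                            cfg.track_length - np.abs(x - cfg.field_center))
                                 > 60.0].mean()
    print(f"{scheme:10s}: summed inhibitory rate in-field {in_field:7.1f} Hz, "
          f"out-of-field {out_field:7.1f} Hz")
pd.DataFrame(profiles).to_csv(OUT / "inhibitory_profiles.csv", index=False)

ca3 = Ca3Population.from_config(cfg)
w = ampar_weight_profile(ca3.centers, cfg.field_center, 2.0,
                         cfg.ampar_floor_width, cfg.track_length)
spatial = ca3.spatial_rate(x)
pd.DataFrame({"x_cm": x, "unweighted_hz": spatial.sum(axis=1),
              "weighted_hz": spatial @ w}).to_csv(OUT / "ca3_drive_profile.csv",
                                                  index=False)
print(f"wrote input summaries to {OUT}/")
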