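#!/usr/bin/env python
"""Evaluate the experimentally derived criterion table on optimized models.

Loads the optimization results written by 03_optimize_variants.py,
re-evaluates each variant's family of degenerate models under the full
protocol, applies the twelve criteria, and writes per-variant criterion
tables plus the cross-variant verdict matrix and the ramp-vs-holding slope
summary to results/report/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ca1ei.optimize import default_parameter_spec, evaluate_candidate
from ca1ei.params import StudyConfig
from ca1ei.report import check_criteria, summarize_fig3
from ca1ei.runner import SimContext, Variant

IN = Path("results/optimization")
OUT = Path("results/report")
OUT.mkdir(parents=True, exist_ok=True)

cfg = StudyConfig()
spec = default_parameter_spec()

matrix = {}
slopes = {}
for manifest_path in sorted(IN.glob("*/manifest.json")):
    manifest = json.loads(manifest_path.read_text())
    label = manifest["variant"]
    scheme, receptors = label.rsplit("_", 1)
    variant = Variant(scheme, receptors == "nmdar")
    ctx = SimContext(cfg, variant, manifest["seed"], n_instances=1, n_trials=5)
    members = []
    for fam in manifest["family"]:
        x = np.array([fam["params"][n] for n in spec.names])
        res = evaluate_candidate(x, ctx, spec)
        members.append(res.features)
    table = check_criteria(members)
    table.to_csv(OUT / f"criteria_{label}.csv", index=False)
    matrix[label] = table.set_index("measurement")["verdict"]
    slopes[label] = [m.slope for m in members]
    print(f"{label}: "
          f"{(table['verdict'] == 'pass').sum()}/12 criteria pass")

pd.DataFrame(matrix).to_csv(OUT / "verdict_matrix.csv")
summarize_fig3(slopes).to_csv(OUT / "slope_summary.csv", index=False)
print(f"wrote criterion tables and slope summary to {OUT}/")
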