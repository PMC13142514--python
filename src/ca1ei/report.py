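"""Criterion matrix and summary tables for optimized model families.

Twelve experimentally derived criteria are checked per model (a row each):
resting Vm, ramp amplitude, the responses to 50% inhibition reduction
(ΔVm and Δtheta amplitude in- and out-of-field, theta phase, precession
change) and to graded depolarization (ramp-vs-holding slope), and the
control theta phase / Δtheta / precession extent. A variant is evaluated on
a family of degenerate low-error models: a criterion is judged *pass* when
at least 4 of 5 family members meet it, *fail* when at most 1 of 5 does,
and reported verbatim as indeterminate in between.

Criteria printed as "target ± tol" are closed intervals. Criteria printed
as "> x ± y" are one-sided with the tolerance belonging to the optimization
softness, so the pass threshold here is x − y (e.g. ΔVm > 1.5 ± 0.5 mV
passes at 1.0 mV). Bare "> x" / "< x" rows compare at face value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .features import FeatureSet, circular_diff_deg

__all__ = ["Criterion", "table_criteria", "check_criteria", "summarize_fig3"]


@dataclass
class Criterion:
    label: str
    perturbation: str
    feature: str
    check: Callable[[float], bool]
    target_text: str

    def passes(self, fs: FeatureSet) -> bool:
        value = getattr(fs, self.feature)
        return bool(np.isfinite(value)) and bool(self.check(value))


def _interval(target, tol, circular=False):
    if circular:
        return lambda v: abs(circular_diff_deg(v, target)) <= tol
    return lambda v: abs(v - target) <= tol


def table_criteria() -> list[Criterion]:
    return [
        Criterion("Resting Vm", "control", "vm_out",
                  _interval(-63.0, 5.0), "-63 ± 5 mV"),
        Criterion("Ramp amplitude (in-out)", "control", "ramp",
                  _interval(6.0, 2.0), "6 ± 2 mV"),
        Criterion("ΔVm (out of field)", "reduced_inh", "dvm_out",
                  lambda v: v >= 1.0, "> 1.5 ± 0.5 mV"),
        Criterion("ΔVm (in field)", "reduced_inh", "dvm_in",
                  lambda v: v >= 1.0, "> 1.5 ± 0.5 mV"),
        Criterion("Ramp amplitude vs holding Vm", "depolarized", "slope",
                  lambda v: v > 0.0, "positive slope"),
        Criterion("Theta phase of Vm peaks", "control", "phase_out_ctrl",
                  _interval(180.0, 20.0, circular=True), "180 ± 20°"),
        Criterion("Theta phase of Vm peaks", "reduced_inh", "phase_out_red",
                  _interval(180.0, 20.0, circular=True), "180 ± 20°"),
        Criterion("ΔTheta amplitude (in-out)", "control", "dtheta_inout",
                  lambda v: v > 0.5, "> 0.5 mV"),
        Criterion("ΔTheta amplitude (out of field)", "reduced_inh", "dtheta_out",
                  lambda v: v > 0.2, "> 0.2 mV"),
        Criterion("ΔTheta amplitude (in field)", "reduced_inh", "dtheta_in",
                  lambda v: v > 0.2, "> 0.2 mV"),
        Criterion("Extent of phase precession", "control", "precession",
                  lambda v: v > 100.0, "> 100°"),
        Criterion("ΔExtent of phase precession", "reduced_inh", "dprecession_pct",
                  lambda v: v < -25.0, "< -25%"),
    ]


def check_criteria(family_features: list[FeatureSet]) -> pd.DataFrame:
    """Evaluate all criteria on one variant's family of models.

    Returns one row per criterion with the per-member pass count and the
    aggregated verdict ("pass" at >= 4/5, "fail" at <= 1/5 by proportion,
    otherwise "indeterminate"; singleton families pass/fail directly).
    """
    n = len(family_features)
    if n == 0:
        raise ValueError("need at least one family member")
    rows = []
    for crit in table_criteria():
        count = sum(crit.passes(f) for f in family_features)
        frac = count / n
        if frac >= 4.0 / 5.0:
            verdict = "pass"
        elif frac <= 1.0 / 5.0:
            verdict = "fail"
        else:
            verdict = "indeterminate"
        rows.append({"perturbation": crit.perturbation, "measurement": crit.label,
                     "target": crit.target_text, "pass_count": count, "n": n,
                     "verdict": verdict})
    return pd.DataFrame(rows)


def summarize_fig3(slopes_by_variant: dict) -> pd.DataFrame:
    """Ramp-vs-holding slope per variant with across-member spread.

    ``slopes_by_variant`` maps a variant label to per-family-member slopes
    (mV/mV).
    """
    rows = []
    for label, slopes in slopes_by_variant.items():
        arr = np.asarray(list(slopes), dtype=float)
        rows.append({"variant": label, "slope_mean": float(arr.mean()),
                     "slope_sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                     "n": int(arr.size)})
    return pd.DataFrame(rows)
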