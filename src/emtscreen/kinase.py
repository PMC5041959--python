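"""Biochemical kinase profiling, the cellular ROCK assay and immunoblot
ratio analysis.

The radiometric kinase assay counts incorporated 33P (cpm).  Per kinase,
the median cpm at full activity with no inhibitor is the high control and
the median cpm without the kinase is the low control; residual activity
of a compound well is

    100 * (cpm - low) / (high - low)   [%]

IC50s come from the variable-slope sigmoid with top fixed at 100% and
bottom at 0%.  The cellular ROCK assay reads myosin-light-chain
phosphorylation, rescaled between a 100 uM Y-27632 low control (mean set
to 0%) and a DMSO high control (mean set to 100%) -- medians for the
biochemical controls, means for the cellular ones, preserving each
assay's own convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .doseresponse import CensoredIC50, FourPLFitError, fit_4pl, ic50_at_50

__all__ = [
    "residual_activity",
    "fit_biochemical_ic50",
    "rock_cellular_activity",
    "BlotQuant",
    "blot_ratio_analysis",
    "AssayWindowError",
    "profile_kinase_plate",
]


class AssayWindowError(ValueError):
    pass


def residual_activity(cpm, high_control_cpm, low_control_cpm):
    """Percent residual kinase activity relative to the median high / low
    cpm controls.  Invariant under affine rescaling of all cpm."""
    high = float(np.median(high_control_cpm))
    low = float(np.median(low_control_cpm))
    if high <= low:
        raise AssayWindowError("high control must exceed low control")
    return 100.0 * (np.asarray(cpm, dtype=float) - low) / (high - low)


def fit_biochemical_ic50(
    concentrations_M,
    residual_activities,
    *,
    ia_threshold_M: float = 1e-5,
) -> CensoredIC50:
    """IC50 from a constrained sigmoid (top = 100%, bottom = 0%) on the
    residual-activity scale; censored "ia" when the fitted curve never
    falls below 50% within the tested range, and flagged extrapolated
    when the crossing lies below the lowest tested concentration."""
    conc_nM = np.asarray(concentrations_M, dtype=float) * 1e9
    activities = np.asarray(residual_activities, dtype=float)
    # activity falls with concentration; fit percent inhibition, which rises
    fit = fit_4pl(conc_nM, 100.0 - activities, fix_top=100.0, fix_bottom=0.0)
    censored = ic50_at_50(
        fit,
        max_tested=ia_threshold_M * 1e9,
        min_tested=float(conc_nM.min()),
        ia_threshold=ia_threshold_M * 1e9,
    )
    return censored


def profile_kinase_plate(plate) -> CensoredIC50:
    """Residual activities + constrained fit for a KinaseAssayPlate."""
    activities = residual_activity(plate.cpm, plate.high_control_cpm,
                                   plate.low_control_cpm)
    return fit_biochemical_ic50(plate.concentrations_M, activities)


def rock_cellular_activity(signal, low_control_signals, high_control_signals):
    """Percent ROCK activity: mean of the Y-27632-treated wells = 0%,
    mean of the DMSO wells = 100%."""
    low = float(np.mean(low_control_signals))
    high = float(np.mean(high_control_signals))
    if high <= low:
        raise AssayWindowError("high control must exceed low control")
    return 100.0 * (np.asarray(signal, dtype=float) - low) / (high - low)


# -- immunoblot quantification ---------------------------------------------


@dataclass(frozen=True)
class BlotQuant:
    """One immunoblot lane: p-SMAD3 and GAPDH signals for a condition in
    one biological replicate."""

    replicate_id: str
    condition_id: str
    psmad3_signal: float
    gapdh_signal: float

    def __post_init__(self):
        if self.psmad3_signal <= 0 or self.gapdh_signal <= 0:
            raise ValueError("blot signals must be positive")

    @property
    def ratio(self) -> float:
        return self.psmad3_signal / self.gapdh_signal


class PairingError(ValueError):
    pass


def blot_ratio_analysis(blots: list[BlotQuant],
                        control_condition: str) -> pd.DataFrame:
    """p-SMAD3/GAPDH ratios per condition with paired t-tests against the
    control condition across biological replicates.

    Every replicate must contain the control lane and each condition's
    lane, otherwise a PairingError is raised.  Returns one row per
    condition with the mean ratio, t statistic and two-sided p-value
    (NaN for the control itself).
    """
    table = pd.DataFrame(
        [(b.replicate_id, b.condition_id, b.ratio) for b in blots],
        columns=["replicate", "condition", "ratio"],
    )
    if table.duplicated(["replicate", "condition"]).any():
        raise PairingError("duplicate lanes for a (replicate, condition) pair")
    wide = table.pivot(index="replicate", columns="condition", values="ratio")
    if control_condition not in wide.columns:
        raise PairingError(f"control condition {control_condition!r} missing")
    rows = []
    for condition in wide.columns:
        pair = wide[[control_condition, condition]].dropna()
        if condition == control_condition:
            rows.append({"condition": condition,
                         "mean_ratio": wide[condition].mean(),
                         "t": math.nan, "p": math.nan, "n": pair.shape[0]})
            continue
        if pair.shape[0] < 2 or pair.shape[0] < wide.shape[0]:
            raise PairingError(
                f"condition {condition!r}: needs >= 2 complete replicate pairs"
            )
        diff = pair[condition] - pair[control_condition]
        if np.allclose(diff, 0):
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat, p_val = stats.ttest_rel(pair[condition],
                                            pair[control_condition])
        rows.append({"condition": condition,
                     "mean_ratio": pair[condition].mean(),
                     "t": float(t_stat), "p": float(p_val),
                     "n": pair.shape[0]})
    return pd.DataFrame(rows)
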