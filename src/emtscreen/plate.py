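"""Plate-level bookkeeping: layouts, control normalization and Z' QC.

Each 384-well screening plate carries TGFb + vehicle wells (mesenchymal
negative controls, 0% effect) and TGFb + 10 uM SB-431542 wells (epithelial
positive controls, 100% effect).  Raw per-well features are rescaled
per plate and readout against its own control means; assay quality is
summarised by the Z'-factor,

    Z' = 1 - 3 * (sigma_p + sigma_n) / |mu_p - mu_n|,

computed from 4 positive and 16 negative control wells.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlateLayout",
    "ROLES",
    "READOUT_COLUMNS",
    "zprime",
    "normalize_percent_effect",
    "toxicity_percent",
    "plate_qc",
]

ROLES = ("negative_control", "positive_control", "dmso_no_tgfb", "treatment")

#: raw feature column -> percent-effect readout name
READOUT_COLUMNS = {
    "fa_per_cell": "FA",
    "sf_per_cell": "SF",
    "fn_per_cell": "FN",
    "nuclei": "CCI",
}

ROW_LETTERS = "ABCDEFGHIJKLMNOP"          # 384-well: rows A-P, columns 1-24
ALL_WELLS = tuple(f"{r}{c:02d}" for r in ROW_LETTERS for c in range(1, 25))


class LayoutError(ValueError):
    pass


@dataclass
class PlateLayout:
    """Well -> (compound, concentration, role) map for one 384-well plate."""

    plate_id: str
    wells: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        for well, info in self.wells.items():
            if well not in ALL_WELLS:
                raise LayoutError(f"{well!r} is not a valid 384-well position")
            if info.get("role") not in ROLES:
                raise LayoutError(f"unknown role {info.get('role')!r} in well {well}")

    def add_well(self, well: str, *, role: str, compound_id: str | None = None,
                 concentration_nM: float | None = None) -> None:
        if well in self.wells:
            raise LayoutError(f"well {well} already assigned")
        if well not in ALL_WELLS:
            raise LayoutError(f"{well!r} is not a valid 384-well position")
        if role not in ROLES:
            raise LayoutError(f"unknown role {role!r}")
        self.wells[well] = {
            "compound_id": compound_id,
            "concentration_nM": concentration_nM,
            "role": role,
        }

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, info in self.wells.items() if info["role"] == role]

    def validate_controls(self, min_negative: int = 16, min_positive: int = 4) -> None:
        n_neg = len(self.wells_with_role("negative_control"))
        n_pos = len(self.wells_with_role("positive_control"))
        if n_neg < min_negative or n_pos < min_positive:
            raise LayoutError(
                f"plate {self.plate_id}: need >= {min_negative} negative and "
                f">= {min_positive} positive control wells, found {n_neg}/{n_pos}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"plate": self.plate_id, "well": well, **info}
            for well, info in sorted(self.wells.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "dict[str, PlateLayout]":
        layouts = {}
        for plate_id, grp in frame.groupby("plate"):
            wells = {}
            for _, row in grp.iterrows():
                conc = row.get("concentration_nM")
                comp = row.get("compound_id")
                wells[row["well"]] = {
                    "compound_id": None if pd.isna(comp) else str(comp),
                    "concentration_nM": None if pd.isna(conc) else float(conc),
                    "role": row["role"],
                }
            layouts[str(plate_id)] = cls(str(plate_id), wells)
        return layouts

    @classmethod
    def read_csv(cls, path) -> "dict[str, PlateLayout]":
        return cls.from_frame(pd.read_csv(path))


def write_platemaps(layouts, path) -> None:
    pd.concat([la.to_frame() for la in layouts]).to_csv(path, index=False)


# -- Z' factor -------------------------------------------------------------


def zprime(pos_values, neg_values) -> float:
    """Z'-factor from positive- and negative-control values.

    Uses sample (n-1) standard deviations and the absolute mean
    difference, making the statistic symmetric under group swap.  Always
    <= 1; negative values indicate overlapping controls.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 values per control group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise ValueError("Z' undefined: control means are equal")
    sd_p = pos.std(ddof=1)
    sd_n = neg.std(ddof=1)
    return 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)


# -- normalization ---------------------------------------------------------


class NormalizationError(ValueError):
    pass


def _control_means(merged: pd.DataFrame, feature: str, floor: float):
    mu_neg = merged.loc[merged["role"] == "negative_control", feature].mean()
    mu_pos = merged.loc[merged["role"] == "positive_control", feature].mean()
    if not np.isfinite(mu_neg) or not np.isfinite(mu_pos):
        raise NormalizationError(f"missing control wells for {feature}")
    if abs(mu_pos - mu_neg) < floor:
        raise NormalizationError(
            f"degenerate controls for {feature}: |mu_pos - mu_neg| < {floor}"
        )
    return mu_neg, mu_pos


def toxicity_percent(nuclei_count, reference_mean: float):
    """Percent toxicity: 0% at the DMSO reference count, 100% at zero
    cells, clipped below at 0 (counts above the reference are not
    'negative toxicity')."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    tox = 100.0 * (reference_mean - np.asarray(nuclei_count, dtype=float)) / reference_mean
    return np.clip(tox, 0.0, None)


def normalize_percent_effect(
    features: pd.DataFrame,
    layouts: dict[str, PlateLayout],
    *,
    degenerate_floor: float = 1e-9,
    tox_reference_role: str = "negative_control",
    compute_toxicity: bool = True,
) -> pd.DataFrame:
    """Rescale raw per-well features to percent effect, per plate.

    effect(x) = 100 * (x - mu_neg) / (mu_pos - mu_neg) for each readout,
    so negative controls average 0% and positive controls 100%.  Values
    outside [0, 100] are legitimate and are not clipped.  Toxicity percent
    is computed from the nuclei count against the mean of the
    ``tox_reference_role`` wells (TGFb + DMSO by default; the screen ran
    every compound in TGFb -- selectable to the no-TGFb DMSO wells).

    ``features`` columns: plate, well, nuclei, fa_per_cell, sf_per_cell,
    fn_per_cell.  Returns a long-format copy with added percent-effect
    columns FA/SF/FN/CCI, tox_pct, compound_id, concentration_nM, role.
    """
    out = []
    for plate_id, grp in features.groupby("plate"):
        plate_id = str(plate_id)
        if plate_id not in layouts:
            raise NormalizationError(f"no layout for plate {plate_id}")
        layout = layouts[plate_id]
        layout.validate_controls()
        # feature tables from the simulator already carry layout columns;
        # the layout is authoritative
        grp = grp.drop(columns=["compound_id", "concentration_nM", "role"],
                       errors="ignore")
        merged = grp.merge(
            layout.to_frame()[["well", "compound_id", "concentration_nM", "role"]],
            on="well", how="left",
        )
        if merged["role"].isna().any():
            missing = merged.loc[merged["role"].isna(), "well"].tolist()
            raise NormalizationError(f"wells without layout entry: {missing}")

        for feature, readout in READOUT_COLUMNS.items():
            mu_neg, mu_pos = _control_means(merged, feature, degenerate_floor)
            merged[readout] = 100.0 * (merged[feature] - mu_neg) / (mu_pos - mu_neg)

        if compute_toxicity:
            ref_wells = merged["role"] == tox_reference_role
            if not ref_wells.any():
                raise NormalizationError(
                    f"no {tox_reference_role} wells for toxicity reference"
                )
            mu_ref = merged.loc[ref_wells, "nuclei"].mean()
            merged["tox_pct"] = toxicity_percent(merged["nuclei"], mu_ref)
        out.append(merged)
    return pd.concat(out, ignore_index=True)


def plate_qc(features: pd.DataFrame, layouts: dict[str, PlateLayout]) -> pd.DataFrame:
    """Per-plate, per-readout Z' from the raw control wells."""
    rows = []
    for plate_id, grp in features.groupby("plate"):
        layout = layouts[str(plate_id)]
        merged = grp.drop(columns=["role"], errors="ignore").merge(
            layout.to_frame()[["well", "role"]], on="well")
        pos = merged[merged["role"] == "positive_control"]
        neg = merged[merged["role"] == "negative_control"]
        for feature, readout in READOUT_COLUMNS.items():
            rows.append({
                "plate": str(plate_id),
                "readout": readout,
                "zprime": zprime(pos[feature], neg[feature]),
            })
    return pd.DataFrame(rows)


def write_qc_json(qc: pd.DataFrame, path) -> None:
    payload = {
        plate: dict(zip(grp["readout"], grp["zprime"].round(4)))
        for plate, grp in qc.groupby("plate")
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def default_control_wells(n_negative: int = 16, n_positive: int = 4,
                          n_dmso: int = 4) -> dict[str, str]:
    """Conventional edge-column control placement: controls live in
    columns 1 and 2, leaving columns 3-24 for treatments."""
    control_positions = [f"{r}{c:02d}" for c in (1, 2) for r in ROW_LETTERS]
    it = iter(control_positions)
    assignment = {}
    for _ in range(n_negative):
        assignment[next(it)] = "negative_control"
    for _ in range(n_positive):
        assignment[next(it)] = "positive_control"
    for _ in range(n_dmso):
        assignment[next(it)] = "dmso_no_tgfb"
    return assignment


def treatment_wells() -> list[str]:
    """Wells available for treatments under the default control placement."""
    return [f"{r}{c:02d}" for r in ROW_LETTERS for c in range(3, 25)]
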