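"""Synthetic screen generator: ground-truth compounds, well features,
rendered micrographs and kinase plates.

The generator emulates the statistical structure of a TGFb-induced EMT
screen in 384-well plates: mesenchymal negative controls (TGFb + vehicle),
epithelial positive controls (TGFb + 10 uM SB-431542), and treated wells
whose per-readout means follow a four-parameter logistic in concentration
between the two control states.  Toxicity acts multiplicatively on the
expected nuclei count through a logistic survival term, reproducing the
confound where cell loss distorts the pattern readouts.  Well-to-well
noise is mean-preserving log-normal, parameterised by a coefficient of
variation: fluorescence-derived per-cell features are positive and
right-skewed.

Default control separations and CVs are chosen so that downstream
Z'-factors from 4 positive / 16 negative control wells land in the
0.4-0.8 band typical of a robust imaging screen.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .plate import (
    PlateLayout,
    default_control_wells,
    treatment_wells,
)
from .segmentation import MicrographSet

__all__ = [
    "TrueCompoundProfile",
    "SimulationConfig",
    "ImagingParams",
    "KinaseAssayPlate",
    "PRIMARY_DOSES_NM",
    "VERIFICATION_DOSES_NM",
    "EXTENDED_DOSES_NM",
    "KINASE_DOSES_M",
    "simulate_compound_truth",
    "build_layouts",
    "simulate_well_features",
    "render_well_images",
    "simulate_kinase_plate",
    "simulate_screen",
    "write_screen",
]

#: primary screen 3-point dilution series (nM)
PRIMARY_DOSES_NM = (3000.0, 300.0, 30.0)
#: verification series used to refine primary hits (nM)
VERIFICATION_DOSES_NM = (3000.0, 1000.0, 300.0, 100.0, 30.0)
#: extended series for re-ordered compounds: 25 uM down to 0.04 nM,
#: half-log-ish 8-point default used in recovery experiments
EXTENDED_DOSES_NM = tuple(25_000.0 / 10 ** (0.75 * i) for i in range(8))
#: biochemical kinase profiling: 10 half-log points, 1e-5 M .. 3e-10 M
KINASE_DOSES_M = tuple(
    1e-5 / 10 ** (0.5 * i) if i % 2 == 0 else 3e-6 / 10 ** (0.5 * (i - 1))
    for i in range(10)
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TrueCompoundProfile:
    """Ground-truth dose-response parameters for one simulated compound.

    Per-readout IC50s (nM) are None for inactive compounds; ``tox_ic50``
    is None for non-toxic compounds.  ``max_effect`` is the plateau
    fraction of the full negative-to-positive control swing.
    """

    compound_id: str
    true_ic50_fa: float | None
    true_ic50_sf: float | None
    true_ic50_fn: float | None
    true_ic50_cci: float | None
    true_hill: float
    true_tox_ic50: float | None
    max_effect: float

    def __post_init__(self):
        for v in (self.true_ic50_fa, self.true_ic50_sf, self.true_ic50_fn,
                  self.true_ic50_cci, self.true_tox_ic50):
            if v is not None and v <= 0:
                raise ConfigurationError("IC50s must be positive")
        if not (0.0 <= self.max_effect <= 1.0):
            raise ConfigurationError("max_effect must lie in [0, 1]")
        if self.true_hill <= 0:
            raise ConfigurationError("hill slope must be positive")

    @property
    def inactive(self) -> bool:
        return self.true_ic50_fa is None

    @property
    def combined_true_ic50(self) -> float | None:
        """Mean of the per-readout pattern IC50s (the recovery target)."""
        if self.inactive:
            return None
        return (self.true_ic50_fa + self.true_ic50_sf + self.true_ic50_fn) / 3.0


# control means: (negative = TGFb+DMSO mesenchymal, positive = TGFb+SB epithelial).
# Pattern readouts fall on EMT blockade; nuclei rise (relief of cell-cycle arrest).
DEFAULT_CONTROL_MEANS = {
    "fa_per_cell": (40.0, 10.0),
    "sf_per_cell": (30.0, 6.0),
    "fn_per_cell": (24.0, 5.0),
    "nuclei": (800.0, 1600.0),
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic screen."""

    n_compounds: int = 48
    dose_series: tuple[float, ...] = EXTENDED_DOSES_NM
    replicate_count: int = 2
    noise_cv: float = 0.10                      # well-to-well CV, pattern readouts
    cell_count_cv: float = 0.04                 # well-to-well CV, nuclei counts
    control_means: dict = field(default_factory=lambda: dict(DEFAULT_CONTROL_MEANS))
    rng_seed: int = 0
    fraction_inactive: float = 0.10
    fraction_toxic: float = 0.10
    ic50_range_nm: tuple[float, float] = (10.0, 10_000.0)
    tox_ic50_range_nm: tuple[float, float] = (2_000.0, 30_000.0)
    hill_range: tuple[float, float] = (0.8, 1.5)
    readout_ic50_log_spread: float = 0.15       # log10 spread of FA/SF/FN around compound IC50
    n_negative_controls: int = 16
    n_positive_controls: int = 4
    n_dmso_controls: int = 4

    def __post_init__(self):
        doses = tuple(float(d) for d in self.dose_series)
        if any(b <= a for a, b in zip(doses[1:], doses)) is False and len(doses) > 1:
            pass
        if len(doses) > 1 and not all(a > b for a, b in zip(doses, doses[1:])):
            raise ConfigurationError("dose_series must be strictly decreasing")
        if self.noise_cv < 0 or self.cell_count_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")
        if self.n_compounds < 0 or self.replicate_count < 1:
            raise ConfigurationError("counts must be positive")
        for key in ("fa_per_cell", "sf_per_cell", "fn_per_cell"):
            neg, pos = self.control_means[key]
            if not neg > pos:
                raise ConfigurationError(
                    f"{key}: negative-control mean must exceed positive-control mean"
                )
        neg, pos = self.control_means["nuclei"]
        if not pos > neg:
            raise ConfigurationError(
                "nuclei: positive-control mean must exceed negative-control mean"
            )
        self.dose_series = doses

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def _logistic_effect(conc: float, ic50: float, hill: float) -> float:
    return 1.0 / (1.0 + (ic50 / conc) ** hill)


def simulate_compound_truth(config: SimulationConfig) -> list[TrueCompoundProfile]:
    """Draw ground-truth compound profiles: IC50s log-uniform over the
    configured range, with designated inactive and toxic fractions.
    Deterministic given the config seed."""
    rng = config.rng()
    n = config.n_compounds
    profiles: list[TrueCompoundProfile] = []
    n_inactive = int(round(config.fraction_inactive * n))
    n_toxic = int(round(config.fraction_toxic * n))
    lo, hi = (math.log10(v) for v in config.ic50_range_nm)
    tlo, thi = (math.log10(v) for v in config.tox_ic50_range_nm)
    for i in range(n):
        cid = f"CPD{i + 1:04d}"
        hill = float(rng.uniform(*config.hill_range))
        inactive = i < n_inactive
        toxic = n_inactive <= i < n_inactive + n_toxic
        tox_ic50 = float(10 ** rng.uniform(tlo, thi)) if toxic else None
        if inactive:
            profiles.append(TrueCompoundProfile(
                cid, None, None, None, None, hill, tox_ic50, 0.0))
            continue
        base = rng.uniform(lo, hi)
        spread = config.readout_ic50_log_spread
        fa, sf, fn = (float(10 ** (base + rng.uniform(-spread, spread)))
                      for _ in range(3))
        cci = float(10 ** (base + rng.uniform(-spread, spread)))
        profiles.append(TrueCompoundProfile(cid, fa, sf, fn, cci, hill,
                                            tox_ic50, 1.0))
    return profiles


def build_layouts(truth: list[TrueCompoundProfile],
                  config: SimulationConfig) -> list[PlateLayout]:
    """Assign every (compound, dose, replicate) to a treatment well,
    filling as many plates as needed; each plate carries the configured
    control wells (columns 1-2)."""
    slots = treatment_wells()
    assignments = [
        (p.compound_id, dose)
        for p in truth
        for dose in config.dose_series
        for _ in range(config.replicate_count)
    ]
    layouts = []
    idx = 0
    plate_no = 0
    while idx < len(assignments) or plate_no == 0:
        plate_no += 1
        layout = PlateLayout(f"P{plate_no:03d}")
        for well, role in default_control_wells(
            config.n_negative_controls, config.n_positive_controls,
            config.n_dmso_controls,
        ).items():
            layout.add_well(well, role=role)
        for well in slots:
            if idx >= len(assignments):
                break
            cid, dose = assignments[idx]
            layout.add_well(well, role="treatment", compound_id=cid,
                            concentration_nM=dose)
            idx += 1
        layouts.append(layout)
    return layouts


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-preserving multiplicative log-normal factors with the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


#: compound IC50 column per raw readout
_READOUT_IC50 = {
    "fa_per_cell": "true_ic50_fa",
    "sf_per_cell": "true_ic50_sf",
    "fn_per_cell": "true_ic50_fn",
    "nuclei": "true_ic50_cci",
}


class MissingCompoundError(KeyError):
    pass


def simulate_well_features(
    truth: list[TrueCompoundProfile],
    layouts: list[PlateLayout],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Generate the per-well feature table plus its noiseless ground truth.

    For each treated well, the noiseless mean of readout r is

        mu_neg_r + effect * (mu_pos_r - mu_neg_r),

    with effect = max_effect / (1 + (ic50_r / conc)**hill); the expected
    nuclei count is further multiplied by a logistic survival term for
    toxic compounds.  Multiplicative log-normal noise with the configured
    CV is then applied.  Columns: plate, well, role, compound_id,
    concentration_nM, the four features, matching expected_* ground-truth
    columns and emt_state (1 = fully mesenchymal).
    """
    for layout in layouts:
        layout.validate_controls(config.n_negative_controls,
                                 config.n_positive_controls)
    by_id = {p.compound_id: p for p in truth}
    rng = config.rng()
    rows = []
    for layout in layouts:
        for well, info in sorted(layout.wells.items()):
            role = info["role"]
            expected = {}
            emt_state = 1.0
            if role in ("negative_control", "treatment"):
                state_idx = 0
            else:  # positive_control and no-TGFb DMSO wells: epithelial
                state_idx = 1
                emt_state = 0.0
            for feat, (neg, pos) in config.control_means.items():
                expected[feat] = (neg, pos)[state_idx]
            if role == "treatment":
                cid = info["compound_id"]
                if cid not in by_id:
                    raise MissingCompoundError(cid)
                prof = by_id[cid]
                conc = info["concentration_nM"]
                for feat, (neg, pos) in config.control_means.items():
                    ic50 = getattr(prof, _READOUT_IC50[feat])
                    eff = 0.0 if ic50 is None else (
                        prof.max_effect * _logistic_effect(conc, ic50, prof.true_hill)
                    )
                    expected[feat] = neg + eff * (pos - neg)
                    if feat == "fa_per_cell":
                        emt_state = 1.0 - eff
                if prof.true_tox_ic50 is not None:
                    survival = 1.0 - _logistic_effect(
                        conc, prof.true_tox_ic50, prof.true_hill)
                    expected["nuclei"] *= survival
            # counting ~1000 nuclei is far less noisy than per-cell
            # fluorescence features; separate CVs reflect that
            noise = {
                feat: _noise_factors(
                    rng,
                    config.cell_count_cv if feat == "nuclei" else config.noise_cv,
                    None,
                )
                for feat in config.control_means
            }
            row = {
                "plate": layout.plate_id,
                "well": well,
                "role": role,
                "compound_id": info["compound_id"],
                "concentration_nM": info["concentration_nM"],
                "emt_state": emt_state,
            }
            for feat, mu in expected.items():
                row[feat] = mu * noise[feat]
                row[f"expected_{feat}"] = mu
            rows.append(row)
    return pd.DataFrame(rows)


# -- micrograph rendering --------------------------------------------------


@dataclass
class ImagingParams:
    """Geometry and noise of the rendered widefield field-of-view."""

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.645          # um/px, 10x widefield sCMOS sampling
    background: float = 100.0          # camera offset, counts
    foreground: float = 3000.0         # object peak intensity, counts
    photon_noise: float = 0.0          # 0 disables shot noise
    n_sites: int = 1

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")


class CapacityError(ValueError):
    pass


def _disk_coords(shape, cy, cx, ry, rx):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _place_centers(rng, shape_px, n, min_dist_px, margin_px, max_tries=8000):
    """Rejection-sample n centers at pairwise distance >= min_dist_px."""
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise CapacityError(
                f"cannot place {n} objects of spacing {min_dist_px:.0f}px "
                f"in a {shape_px} frame"
            )
        cy = rng.uniform(margin_px, shape_px[0] - margin_px)
        cx = rng.uniform(margin_px, shape_px[1] - margin_px)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_dist_px ** 2
               for y, x in centers):
            centers.append((cy, cx))
    return centers


def _ring_layout(n: int, nucleus_radius_um: float, *,
                 spacing_um: float = 5.0, gap_um: float = 4.5):
    """Distribute n puncta over concentric rings outside the nucleus so
    that centers are >= spacing_um apart along each ring and rings are
    gap_um apart (puncta are at most 3 um wide, so none touch)."""
    rings = []
    r = 1.3 * nucleus_radius_um + 2.0
    remaining = n
    while remaining > 0:
        capacity = max(1, int(2 * math.pi * r // spacing_um))
        take = min(capacity, remaining)
        rings.append((r, take))
        remaining -= take
        r += gap_um
    return rings


def _ring_radii(n: int, nucleus_radius_um: float) -> list[float]:
    return [r for r, _ in _ring_layout(n, nucleus_radius_um)]


def _draw_line(img, y0, x0, y1, x1, value, width=1):
    n = int(max(abs(y1 - y0), abs(x1 - x0)) * 2) + 2
    ys = np.linspace(y0, y1, n)
    xs = np.linspace(x0, x1, n)
    h, w = img.shape
    r = width // 2
    for y, x in zip(ys, xs):
        yi, xi = int(round(y)), int(round(x))
        img[max(0, yi - r): yi + r + 1, max(0, xi - r): xi + r + 1] = value


def render_well_images(
    expected_nuclei: int,
    expected_fa_per_cell: float,
    expected_sf_per_cell: float,
    expected_fn_per_cell: float,
    imaging: ImagingParams = ImagingParams(),
    *,
    well_id: str = "A01",
    rng: np.random.Generator | None = None,
) -> list[tuple[MicrographSet, dict]]:
    """Render per-site four-channel micrographs for one well.

    DAPI: ellipsoidal nuclei, equivalent diameters drawn from 9-16 um.
    FITC: 1-3 um puncta ringed around each nucleus (focal adhesions sit
    near cell borders), ``expected_fa_per_cell`` per cell.  TxRed / Cy5:
    short straight fibers whose skeleton decomposes into one segment and
    two endpoint nodes each, so that (S + B + N) per cell approximates the
    expected stress-fiber / fibronectin score.  Returns, per site, the
    image set and a ground-truth dict of the drawn object counts.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    px = imaging.pixel_size
    shape = imaging.image_shape
    sites = []
    for site in range(imaging.n_sites):
        channels = {
            ch: np.full(shape, imaging.background, dtype=float)
            for ch in ("DAPI", "FITC", "TxRed", "Cy5")
        }
        truth = {"nuclei": expected_nuclei, "fa_puncta": 0,
                 "sf_fibers": 0, "fn_fibers": 0}
        if expected_nuclei > 0:
            # nucleus diameters 9-16 um; cell spacing reserves room for the
            # focal-adhesion rings so puncta of neighboring cells never touch
            max_diam_px = 16.0 / px
            n_puncta = int(round(expected_fa_per_cell))
            ring_radii = _ring_radii(n_puncta, max_diam_px * px / 2.0)
            reach_um = (ring_radii[-1] + 2.0) if ring_radii else max_diam_px * px * 0.6
            spacing = max(3.2 * max_diam_px, (2 * reach_um + 2.0) / px)
            centers = _place_centers(rng, shape, expected_nuclei, spacing,
                                     margin_px=spacing / 2.0)
            for cy, cx in centers:
                # interior of the 9-16 um detection window: pixelation can
                # inflate the measured equivalent diameter by ~1 px
                eq_diam = rng.uniform(9.5, 15.0) / px
                aspect = rng.uniform(0.8, 1.25)
                ry = (eq_diam / 2.0) * math.sqrt(aspect)
                rx = (eq_diam / 2.0) / math.sqrt(aspect)
                channels["DAPI"][_disk_coords(shape, cy, cx, ry, rx)] = (
                    imaging.foreground)

                # FITC puncta on concentric rings outside the nucleus
                if n_puncta > 0:
                    placed = 0
                    for ring_um, n_on_ring in _ring_layout(n_puncta,
                                                           max_diam_px * px / 2.0):
                        ring_r = ring_um / px
                        phase = rng.uniform(0, 2 * math.pi)
                        for k in range(n_on_ring):
                            ang = phase + 2 * math.pi * k / n_on_ring
                            py = cy + ring_r * math.sin(ang)
                            px_ = cx + ring_r * math.cos(ang)
                            pr = rng.uniform(1.0, 3.0) / (2 * px)  # 1-3 um dia
                            mask = _disk_coords(shape, py, px_, pr, pr)
                            channels["FITC"][mask] = imaging.foreground
                            placed += 1
                    truth["fa_puncta"] += placed

                # fibers: each contributes S=1, B=0, N=2 -> score 3
                for ch_name, score, key in (
                    ("TxRed", expected_sf_per_cell, "sf_fibers"),
                    ("Cy5", expected_fn_per_cell, "fn_fibers"),
                ):
                    n_fibers = int(round(score / 3.0))
                    if n_fibers == 0:
                        continue
                    length_px = 3.0 / px
                    ring0 = 1.1 * eq_diam
                    for k in range(n_fibers):
                        ang = rng.uniform(0, 2 * math.pi) if n_fibers == 1 else (
                            2 * math.pi * k / n_fibers + rng.uniform(-0.05, 0.05))
                        fr = ring0 + (k % 3) * (length_px + 6)
                        fy = cy + fr * math.sin(ang)
                        fx = cx + fr * math.cos(ang)
                        _draw_line(channels[ch_name],
                                   fy, fx,
                                   fy + length_px * math.sin(ang),
                                   fx + length_px * math.cos(ang),
                                   imaging.foreground, width=2)
                        truth[key] += 1

        if imaging.photon_noise > 0:
            for ch in channels:
                lam = channels[ch] / imaging.photon_noise
                channels[ch] = rng.poisson(lam) * imaging.photon_noise

        channels = {
            ch: np.clip(img, 0, 65535).astype(np.uint16)
            for ch, img in channels.items()
        }
        sites.append((
            MicrographSet(channels=channels, pixel_size=px,
                          site_id=f"s{site + 1}", well_id=well_id),
            truth,
        ))
    return sites


# -- kinase plates ---------------------------------------------------------


@dataclass
class KinaseAssayPlate:
    """One kinase x one compound: cpm at each concentration plus high/low
    control replicate wells."""

    kinase_id: str
    concentrations_M: tuple[float, ...]
    cpm: np.ndarray
    high_control_cpm: np.ndarray
    low_control_cpm: np.ndarray


def simulate_kinase_plate(
    true_ic50_M: float,
    hill: float,
    *,
    kinase_id: str = "KIN",
    doses_M: tuple[float, ...] = KINASE_DOSES_M,
    high_cpm: float = 4000.0,
    low_cpm: float = 200.0,
    n_control_wells: int = 4,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> KinaseAssayPlate:
    """Radiometric kinase-assay plate: cpm = low + (high - low) * residual
    activity, residual activity following a descending logistic in
    concentration.  Poisson count noise unless ``noise=False``."""
    if high_cpm <= low_cpm:
        raise ConfigurationError("high control cpm must exceed low control cpm")
    if true_ic50_M <= 0 or hill <= 0:
        raise ConfigurationError("IC50 and hill must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    doses = np.asarray(doses_M, dtype=float)
    residual = 1.0 / (1.0 + (doses / true_ic50_M) ** hill)
    cpm = low_cpm + (high_cpm - low_cpm) * residual
    high = np.full(n_control_wells, high_cpm, dtype=float)
    low = np.full(n_control_wells, low_cpm, dtype=float)
    if noise:
        cpm = rng.poisson(cpm).astype(float)
        high = rng.poisson(high).astype(float)
        low = rng.poisson(low).astype(float)
    return KinaseAssayPlate(kinase_id, tuple(doses), cpm, high, low)


# -- orchestration / IO ----------------------------------------------------


def simulate_screen(config: SimulationConfig):
    """Truth + layouts + well-feature table in one call."""
    truth = simulate_compound_truth(config)
    layouts = build_layouts(truth, config)
    features = simulate_well_features(truth, layouts, config)
    return truth, layouts, features


def write_screen(config: SimulationConfig, out_dir, *, images: bool = False) -> dict:
    """Write plate-map, feature and ground-truth CSVs (and optionally
    per-site TIFF stacks) plus a JSON manifest; returns the manifest."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, layouts, features = simulate_screen(config)

    platemap = pd.concat([la.to_frame() for la in layouts])
    platemap.to_csv(out / "platemap.csv", index=False)

    feature_cols = ["plate", "well", "nuclei", "fa_per_cell", "sf_per_cell",
                    "fn_per_cell"]
    features[feature_cols].assign(n_sites_used=1).to_csv(
        out / "wells.csv", index=False)

    truth_df = pd.DataFrame([asdict(p) for p in truth])
    truth_df.to_csv(out / "ground_truth_compounds.csv", index=False)
    gt_cols = ["plate", "well", "emt_state"] + [
        c for c in features.columns if c.startswith("expected_")]
    features[gt_cols].to_csv(out / "ground_truth_wells.csv", index=False)

    if images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        imaging = ImagingParams()
        rng = np.random.default_rng(config.rng_seed + 1)
        for _, row in features.iterrows():
            # image rendering scales per-well counts down to one field of view
            scale = max(1, int(row["expected_nuclei"] // 50))
            sites = render_well_images(
                max(0, int(round(row["expected_nuclei"] / scale / 10))),
                row["expected_fa_per_cell"],
                row["expected_sf_per_cell"],
                row["expected_fn_per_cell"],
                imaging, well_id=row["well"], rng=rng,
            )
            for mset, _ in sites:
                for ch, img in mset.channels.items():
                    tifffile.imwrite(
                        img_dir / f"{row['plate']}_{row['well']}_{mset.site_id}_{ch}.tif",
                        img,
                    )

    manifest = {
        "seed": config.rng_seed,
        "n_compounds": config.n_compounds,
        "dose_series_nM": list(config.dose_series),
        "replicate_count": config.replicate_count,
        "noise_cv": config.noise_cv,
        "n_plates": len(layouts),
        "images": bool(images),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
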