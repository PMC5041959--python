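"""Four-parameter logistic dose-response modelling and compound profiling.

The screen's compound-level quantities all derive from a four-parameter
logistic (4PL) curve with variable slope,

    y(x) = bottom + (top - bottom) / (1 + (ic50 / x)**hill),

fitted by least squares on the percent-effect scale, where 0% is the
TGFb + vehicle negative control (mesenchymal state) and 100% is the
TGFb + 10 uM SB-431542 positive control (epithelial state).  From the
fitted curve we report the concentration at which each readout crosses
50% effect, censored when no crossing occurs in the tested range:

``ia``
    inactive -- no 50% crossing below the top tested concentration
    (>= 25 uM in the verification series).
``n.m.``
    not measurable -- no crossing at non-toxic concentrations.
``n.d.``
    not determined -- the fit did not converge.

The combined EMT IC50 of a compound is the arithmetic mean of its focal
adhesion (FA), stress fiber (SF) and fibronectin (FN) IC50s, defined only
when all three were measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "FourParamLogistic",
    "FourPLResults",
    "CensoredIC50",
    "CompoundProfile",
    "HitRule",
    "HitCall",
    "four_pl",
    "fit_4pl",
    "ic50_at_50",
    "tox_ic50",
    "emax_cci",
    "combined_emt_ic50",
    "call_hit",
    "toxicity_flag",
    "fit_compound_profiles",
    "IA_THRESHOLD_NM",
]

#: top concentration of the extended verification dilution series (25 uM);
#: compounds with no 50% crossing below this bound are reported "ia".
IA_THRESHOLD_NM = 25_000.0

PATTERN_READOUTS = ("FA", "SF", "FN")


def four_pl(x, top, bottom, ic50, hill):
    """Evaluate the variable-slope logistic at concentration(s) ``x``."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        return bottom + (top - bottom) / (1.0 + (ic50 / x) ** hill)


class FourPLFitError(ValueError):
    """Raised when a dose-response fit cannot be attempted."""


@dataclass
class FourPLResults:
    """Results of a :class:`FourParamLogistic` fit.

    Attributes
    ----------
    top, bottom : float
        Upper / lower plateaus on the percent-effect scale.
    ic50 : float
        Inflection concentration (same units as the model's ``conc``, nM
        throughout this package).
    hill : float
        Slope factor, constrained positive.
    rss : float
        Residual sum of squares of the best fit.
    converged : bool
        False when the optimiser failed or the curve explains no more
        variance than a flat line (no dose dependence).
    """

    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    nobs: int = 0
    model: "FourParamLogistic | None" = field(default=None, repr=False)

    @property
    def params(self) -> dict[str, float]:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "ic50": self.ic50,
            "hill": self.hill,
        }

    def predict(self, conc) -> np.ndarray:
        return four_pl(conc, self.top, self.bottom, self.ic50, self.hill)

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic fit",
            "=" * 43,
            f"{'n obs':<14}{self.nobs:>12}",
            f"{'converged':<14}{str(self.converged):>12}",
            f"{'RSS':<14}{self.rss:>12.4g}",
            "-" * 43,
        ]
        for name, value in self.params.items():
            lines.append(f"{name:<14}{value:>12.4g}")
        lines.append("=" * 43)
        return "\n".join(lines)


class FourParamLogistic:
    """Four-parameter logistic dose-response model.

    Parameters
    ----------
    conc : array-like
        Concentrations, strictly positive (nM).
    response : array-like
        Observed responses, typically percent effect.
    fix_top, fix_bottom : float, optional
        Pin a plateau (e.g. ``fix_top=100, fix_bottom=0`` for the
        constrained sigmoid used in biochemical kinase profiling).

    ``fit()`` multi-starts the IC50 at every tested concentration decade
    and keeps the solution with the lowest residual sum of squares,
    breaking ties toward the lower IC50.
    """

    #: hill-slope search bounds; generous relative to experimental slopes
    HILL_BOUNDS = (1e-2, 20.0)

    def __init__(self, conc, response, *, fix_top=None, fix_bottom=None):
        conc = np.asarray(conc, dtype=float)
        response = np.asarray(response, dtype=float)
        if conc.shape != response.shape:
            raise FourPLFitError("conc and response must have the same length")
        if np.any(conc <= 0):
            raise FourPLFitError("concentrations must be strictly positive")
        if not np.all(np.isfinite(response)):
            raise FourPLFitError("responses must be finite")
        if np.unique(conc).size < 4:
            raise FourPLFitError(
                "at least 4 distinct concentrations are required for a 4PL fit"
            )
        self.conc = conc
        self.response = response
        self.fix_top = fix_top
        self.fix_bottom = fix_bottom

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, conc_col: str = "concentration_nM",
                       response_col: str = "effect", **kwargs) -> "FourParamLogistic":
        return cls(data[conc_col].to_numpy(), data[response_col].to_numpy(), **kwargs)

    # -- fitting -----------------------------------------------------------

    def _pack(self, top, bottom, log_ic50, hill):
        free = []
        if self.fix_top is None:
            free.append(top)
        if self.fix_bottom is None:
            free.append(bottom)
        free.extend([log_ic50, hill])
        return np.array(free, dtype=float)

    def _unpack(self, theta):
        i = 0
        if self.fix_top is None:
            top = theta[i]; i += 1
        else:
            top = self.fix_top
        if self.fix_bottom is None:
            bottom = theta[i]; i += 1
        else:
            bottom = self.fix_bottom
        log_ic50, hill = theta[i], theta[i + 1]
        return top, bottom, 10.0 ** log_ic50, hill

    def _residuals(self, theta):
        top, bottom, ic50, hill = self._unpack(theta)
        return four_pl(self.conc, top, bottom, ic50, hill) - self.response

    def fit(self) -> FourPLResults:
        y = self.response
        tss = float(np.sum((y - y.mean()) ** 2))

        top0 = self.fix_top if self.fix_top is not None else float(y.max())
        bot0 = self.fix_bottom if self.fix_bottom is not None else float(y.min())
        hill0 = 1.0

        lo = math.floor(math.log10(self.conc.min()))
        hi = math.ceil(math.log10(self.conc.max()))
        starts = np.arange(lo, hi + 1, dtype=float)  # one start per decade

        lb, ub = [], []
        if self.fix_top is None:
            lb.append(-np.inf); ub.append(np.inf)
        if self.fix_bottom is None:
            lb.append(-np.inf); ub.append(np.inf)
        lb.extend([lo - 3.0, self.HILL_BOUNDS[0]])
        ub.extend([hi + 3.0, self.HILL_BOUNDS[1]])

        best = None
        for log_ic50_0 in starts:
            theta0 = self._pack(top0, bot0, log_ic50_0, hill0)
            try:
                sol = optimize.least_squares(
                    self._residuals, theta0, bounds=(lb, ub), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(2.0 * sol.cost)
            top, bottom, ic50, hill = self._unpack(sol.x)
            cand = (rss, ic50, top, bottom, hill)
            if best is None or (cand[0] < best[0] - 1e-12 * max(1.0, best[0])) or (
                abs(cand[0] - best[0]) <= 1e-12 * max(1.0, best[0]) and cand[1] < best[1]
            ):
                best = cand

        if best is None:
            return FourPLResults(np.nan, np.nan, np.nan, np.nan, np.inf,
                                 converged=False, nobs=y.size, model=self)
        rss, ic50, top, bottom, hill = best
        converged = tss > 0 and rss < tss
        return FourPLResults(top, bottom, ic50, hill, rss,
                             converged=converged, nobs=y.size, model=self)


def fit_4pl(concentrations, responses, *, fix_top=None, fix_bottom=None) -> FourPLResults:
    """Functional wrapper around :class:`FourParamLogistic`."""
    return FourParamLogistic(
        concentrations, responses, fix_top=fix_top, fix_bottom=fix_bottom
    ).fit()


# -- censored IC50s --------------------------------------------------------

_STATUS_LABEL = {
    "measured": "",
    "inactive_above_max": "ia",
    "not_measurable": "n.m.",
    "not_determined": "n.d.",
}


@dataclass(frozen=True)
class CensoredIC50:
    """An IC50 with its censoring status.

    ``value`` is set only when ``status == "measured"``.  ``extrapolated``
    marks crossings below the lowest tested concentration, reported in
    tables as ``<lowest`` rather than as a numeric claim.
    """

    status: str
    value: float | None = None
    max_tested: float | None = None
    extrapolated: bool = False

    def __post_init__(self):
        if self.status not in _STATUS_LABEL:
            raise ValueError(f"unknown censoring status: {self.status!r}")
        if (self.value is not None) != (self.status == "measured"):
            raise ValueError("value must be present iff status is 'measured'")

    @classmethod
    def measured(cls, value, max_tested=None, extrapolated=False):
        return cls("measured", float(value), max_tested, extrapolated)

    @property
    def is_measured(self) -> bool:
        return self.status == "measured"

    @property
    def label(self) -> str:
        """Table representation: a number, '<lowest', 'ia', 'n.m.' or 'n.d.'."""
        if self.is_measured:
            if self.extrapolated:
                return f"<{self.value:g}"
            return f"{round(self.value, 1):g}"
        return _STATUS_LABEL[self.status]

    def __float__(self) -> float:
        return self.value if self.is_measured else math.nan


def _crossing(results: FourPLResults, level: float):
    """Concentration where the fitted curve crosses ``level``, or None.

    Solved numerically by bisection on log-concentration; the closed form
    ic50 * ((top-level)/(level-bottom))**(-1/hill) serves as the oracle in
    the test suite.
    """
    top, bottom, hill = results.top, results.bottom, results.hill
    lo_l, hi_l = sorted((top, bottom))
    if not (lo_l < level < hi_l):
        return None

    def f(log_x):
        return float(results.predict(10.0 ** log_x) - level)

    # the crossing lies at the closed-form point; bracket it generously
    center = math.log10(results.ic50)
    a, b = center - 12.0, center + 12.0
    fa, fb = f(a), f(b)
    if fa == 0.0:
        return 10.0 ** a
    if fa * fb > 0:  # pathological slope; widen once
        a, b = center - 30.0, center + 30.0
        fa, fb = f(a), f(b)
        if fa * fb > 0:
            return None
    return 10.0 ** optimize.brentq(f, a, b, xtol=1e-13, rtol=8.9e-16)


def ic50_at_50(
    results: FourPLResults,
    *,
    max_tested: float,
    min_tested: float | None = None,
    tox_limit: float | None = None,
    level: float = 50.0,
    ia_threshold: float = IA_THRESHOLD_NM,
) -> CensoredIC50:
    """Concentration at which the fitted percent-effect curve crosses 50%.

    Parameters
    ----------
    max_tested : float
        Top concentration of the dilution series (nM); bounds the "ia"
        censoring.
    min_tested : float, optional
        Lowest tested concentration; crossings below it are flagged
        extrapolated.
    tox_limit : float, optional
        The compound's toxicity IC50.  A crossing at or above it is not a
        measurable effect at non-toxic concentrations ("n.m.").
    """
    if not results.converged:
        # a flat response is not a failed measurement: when the observed
        # responses sit clearly below the 50% level the compound showed no
        # measurable effect and is censored like any non-crossing curve;
        # flat-at-high or failed optimizations stay "n.d."
        obs = results.model.response if results.model is not None else None
        if obs is not None and np.mean(obs) < level:
            if max_tested >= ia_threshold:
                return CensoredIC50("inactive_above_max", max_tested=max_tested)
            return CensoredIC50("not_measurable", max_tested=max_tested)
        return CensoredIC50("not_determined", max_tested=max_tested)
    x = _crossing(results, level)
    if x is None or x > max_tested:
        if max_tested >= ia_threshold:
            return CensoredIC50("inactive_above_max", max_tested=max_tested)
        return CensoredIC50("not_measurable", max_tested=max_tested)
    if tox_limit is not None and x >= tox_limit:
        return CensoredIC50("not_measurable", max_tested=max_tested)
    extrapolated = min_tested is not None and x < min_tested
    return CensoredIC50.measured(x, max_tested, extrapolated=extrapolated)


def tox_ic50(results: FourPLResults, *, max_tested: float,
             min_tested: float | None = None) -> CensoredIC50:
    """50% crossing of the toxicity-percent curve (0% = DMSO reference,
    100% = zero cells); censored "ia" when no crossing occurs below the
    top tested concentration."""
    return ic50_at_50(results, max_tested=max_tested, min_tested=min_tested)


def emax_cci(
    effects: Mapping[float, float] | pd.Series,
    tox_percents: Mapping[float, float] | pd.Series | None = None,
    *,
    tox_cut: float = 50.0,
) -> float | None:
    """Maximal cell-count-increase percent effect across tested
    concentrations, restricted to non-toxic concentrations.

    Returns None (undefined) when every tested concentration is toxic.
    """
    effects = dict(effects)
    if not effects:
        raise ValueError("at least one concentration is required")
    if tox_percents is not None:
        tox = dict(tox_percents)
        effects = {c: e for c, e in effects.items() if tox.get(c, 0.0) <= tox_cut}
    if not effects:
        return None
    return float(max(effects.values()))


_CENSOR_SEVERITY = ("not_determined", "not_measurable", "inactive_above_max")


def combined_emt_ic50(ic50_fa: CensoredIC50, ic50_sf: CensoredIC50,
                      ic50_fn: CensoredIC50) -> CensoredIC50:
    """Mean of the FA, SF and FN IC50s; defined only when all three are
    measured, otherwise the least-informative censoring label propagates
    (n.d. over n.m. over ia)."""
    parts = (ic50_fa, ic50_sf, ic50_fn)
    if all(p.is_measured for p in parts):
        mean = sum(p.value for p in parts) / 3.0
        max_tested = max((p.max_tested for p in parts if p.max_tested), default=None)
        return CensoredIC50.measured(
            mean, max_tested, extrapolated=any(p.extrapolated for p in parts)
        )
    statuses = {p.status for p in parts if not p.is_measured}
    for status in _CENSOR_SEVERITY:
        if status in statuses:
            max_tested = max((p.max_tested for p in parts if p.max_tested), default=None)
            return CensoredIC50(status, max_tested=max_tested)
    raise AssertionError("unreachable")


# -- hit calling -----------------------------------------------------------


@dataclass(frozen=True)
class HitRule:
    """Primary-screen hit thresholds (strict inequalities)."""

    cci_threshold: float = 10.0
    single_readout_threshold: float = 60.0
    double_readout_threshold: float = 40.0
    tox_cut: float = 50.0


@dataclass(frozen=True)
class HitCall:
    hit: bool | None            # None = not evaluable (all concentrations toxic)
    clause: str | None          # 'cci' | 'single_readout' | 'double_readout'
    concentration: float | None


def call_hit(effects: pd.DataFrame, rule: HitRule = HitRule()) -> HitCall:
    """Apply the primary-screen hit rule per concentration.

    ``effects`` has one row per tested concentration with columns
    ``concentration_nM``, ``FA``, ``SF``, ``FN``, ``CCI`` (percent effects)
    and optionally ``tox_pct``.  A compound is a hit if, at any single
    non-toxic concentration, CCI exceeds 10%, or one pattern readout
    exceeds 60%, or two pattern readouts exceed 40% (all strict).  Clause
    precedence when several fire at the same concentration: cci, then
    single, then double; concentrations are scanned in increasing order.
    """
    rows = effects.sort_values("concentration_nM")
    any_evaluable = False
    for _, row in rows.iterrows():
        if "tox_pct" in rows.columns and row["tox_pct"] > rule.tox_cut:
            continue
        any_evaluable = True
        conc = float(row["concentration_nM"])
        if row["CCI"] > rule.cci_threshold:
            return HitCall(True, "cci", conc)
        pattern = [row[r] for r in PATTERN_READOUTS]
        if any(v > rule.single_readout_threshold for v in pattern):
            return HitCall(True, "single_readout", conc)
        if sum(v > rule.double_readout_threshold for v in pattern) >= 2:
            return HitCall(True, "double_readout", conc)
    if not any_evaluable:
        return HitCall(None, None, None)
    return HitCall(False, None, None)


def toxicity_flag(nuclei_count: float, reference_count: float) -> bool:
    """Cytotoxicity at the screening concentration: cell count reduced by
    more than 50% relative to the DMSO reference (strict)."""
    if reference_count <= 0:
        raise ValueError("reference count must be positive")
    return nuclei_count < 0.5 * reference_count


# -- compound profiles -----------------------------------------------------


@dataclass
class CompoundProfile:
    """Per-compound screen summary mirroring the published hit table."""

    compound_id: str
    ic50_fa: CensoredIC50
    ic50_sf: CensoredIC50
    ic50_fn: CensoredIC50
    ic50_cci: CensoredIC50
    ic50_tox: CensoredIC50
    emax_cci: float | None
    combined_emt_ic50: CensoredIC50
    hit: bool | None
    hit_clause: str | None = None
    fits: dict[str, FourPLResults] = field(default_factory=dict, repr=False)

    def to_row(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "ic50_fa": self.ic50_fa.label,
            "ic50_sf": self.ic50_sf.label,
            "ic50_fn": self.ic50_fn.label,
            "ic50_cci": self.ic50_cci.label,
            "ic50_tox": self.ic50_tox.label,
            "emax_cci": "" if self.emax_cci is None else round(self.emax_cci, 1),
            "combined_emt_ic50": self.combined_emt_ic50.label,
            "hit": "" if self.hit is None else bool(self.hit),
            "hit_clause": self.hit_clause or "",
        }


def _mean_effects(group: pd.DataFrame) -> pd.DataFrame:
    """Average replicate wells at each concentration."""
    cols = [c for c in ("FA", "SF", "FN", "CCI", "tox_pct") if c in group.columns]
    return group.groupby("concentration_nM", as_index=False)[cols].mean()


def fit_compound_profiles(
    normalized: pd.DataFrame,
    *,
    hit_rule: HitRule = HitRule(),
    min_points: int = 4,
) -> list[CompoundProfile]:
    """Fit 4PL curves per compound and readout and assemble profiles.

    ``normalized`` is the long table written by the normalization stage:
    one row per treated well with columns ``compound_id``,
    ``concentration_nM``, percent effects ``FA``/``SF``/``FN``/``CCI`` and
    ``tox_pct``.
    """
    profiles = []
    treated = normalized[normalized["compound_id"].notna()]
    for compound_id, group in treated.groupby("compound_id", sort=True):
        concs = np.sort(group["concentration_nM"].unique())
        max_tested = float(concs.max())
        min_tested = float(concs.min())

        fits: dict[str, FourPLResults] = {}

        def _fit(col: str, **constraints) -> FourPLResults | None:
            if np.unique(group["concentration_nM"]).size < min_points:
                return None
            try:
                return fit_4pl(group["concentration_nM"], group[col],
                               **constraints)
            except FourPLFitError:
                return None

        def _censored(col: str, tox_limit=None, **constraints) -> CensoredIC50:
            res = _fit(col, **constraints)
            if res is None:
                return CensoredIC50("not_determined", max_tested=max_tested)
            fits[col] = res
            return ic50_at_50(res, max_tested=max_tested, min_tested=min_tested,
                              tox_limit=tox_limit)

        # toxicity is zero by definition at zero dose; pinning the lower
        # plateau keeps a noisy near-flat curve from crossing 50% spuriously
        tox = _censored("tox_pct", fix_bottom=0.0)
        tox_limit = tox.value if tox.is_measured else None
        fa = _censored("FA", tox_limit)
        sf = _censored("SF", tox_limit)
        fn = _censored("FN", tox_limit)
        cci = _censored("CCI", tox_limit)

        per_conc = _mean_effects(group)
        emax = emax_cci(
            per_conc.set_index("concentration_nM")["CCI"],
            per_conc.set_index("concentration_nM")["tox_pct"]
            if "tox_pct" in per_conc.columns else None,
            tox_cut=hit_rule.tox_cut,
        )
        hit = call_hit(per_conc, hit_rule)
        profiles.append(CompoundProfile(
            compound_id=str(compound_id),
            ic50_fa=fa, ic50_sf=sf, ic50_fn=fn, ic50_cci=cci, ic50_tox=tox,
            emax_cci=emax,
            combined_emt_ic50=combined_emt_ic50(fa, sf, fn),
            hit=hit.hit, hit_clause=hit.clause, fits=fits,
        ))
    return profiles


def profiles_to_frame(profiles: Sequence[CompoundProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.to_row() for p in profiles])
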