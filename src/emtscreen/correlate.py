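"""Cross-readout correlation reports (Spearman with exact small-n p)."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SpearmanResult", "spearman", "spearman_matrix"]


@dataclass(frozen=True)
class SpearmanResult:
    x: str
    y: str
    r: float
    p: float
    n: int


class DegenerateDataError(ValueError):
    pass


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of average ranks (the Spearman coefficient)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise DegenerateDataError("all values tied; correlation undefined")
    return float(rx @ ry) / denom


def spearman(x, y, *, exact_n_max: int = 9) -> SpearmanResult:
    """Spearman rank correlation with two-sided p-value.

    Ties receive average ranks.  For n <= ``exact_n_max`` the p-value is
    an exact permutation tail (all n! orderings enumerated); above that,
    the usual t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise DegenerateDataError("need >= 3 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = _rank_corr(rx, ry)

    if n <= exact_n_max:
        count = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_corr(rx, np.asarray(perm))) >= abs(r) - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return SpearmanResult("x", "y", r, p, n)


def spearman_matrix(table: pd.DataFrame,
                    pairs: list[tuple[str, str]] | None = None,
                    *, drop_censored: bool = True) -> pd.DataFrame:
    """Pairwise Spearman correlations between table columns.

    Censored entries (non-numeric labels such as 'ia' / 'n.m.' / 'n.d.')
    are excluded pairwise by default, matching how censored IC50s are
    left off correlation scatters.  Returns a long-format report with
    columns x, y, r, p, n.
    """
    if pairs is None:
        cols = list(table.columns)
        pairs = list(itertools.combinations(cols, 2))
    rows = []
    for cx, cy in pairs:
        x = pd.to_numeric(table[cx], errors="coerce" if drop_censored else "raise")
        y = pd.to_numeric(table[cy], errors="coerce" if drop_censored else "raise")
        res = spearman(x.to_numpy(), y.to_numpy())
        rows.append({"x": cx, "y": cy, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)
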