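"""Per-CpG simple linear regression of beta on chronological age.

Each CpG row is fit independently by ordinary least squares: slope (beta
units per year), intercept (beta at age 0), coefficient of determination R²,
and a two-sided p-value from the slope t-test,

    t = sign(slope) * sqrt(R² (n-2) / (1 - R²)),   p = 2 P(T_{n-2} >= |t|).

The fit is vectorized across rows but numerically identical to independent
per-row fits.  Hypomethylation with age is a negative slope, hypermethylation
a positive one.  Benjamini-Hochberg q-values are attached for reporting; the
significance filters operate on raw p and R², mirroring common practice in
small-cohort methylation-ageing screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import BetaMatrix
from .io import CpGSite

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgeRegressionRow:
    site: CpGSite
    mod_code: str
    n: int
    slope: float
    intercept: float
    r2: float
    p: float
    q: float
    direction: str  # positive | negative | flat

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs >= 3 observations")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 out of range: {self.r2}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


def fit_age_regression(
    m: BetaMatrix, flat_epsilon: float = 0.0, min_n: int = 3
) -> list[AgeRegressionRow]:
    """OLS of beta on age for every site of a matrix.

    Missing entries are allowed: each row uses its observed subset (per-row n).
    Rows with fewer than ``min_n`` observations, or whose observed ages are all
    equal, are skipped with a logged count.  Constant-beta rows (Syy = 0) get
    slope 0, R² 0, p 1.
    """
    ages = m.ages
    if np.ptp(ages) == 0:
        raise ValueError("all sample ages are equal; regression is undefined")
    beta = m.beta
    obs = ~np.isnan(beta)
    n = obs.sum(axis=1)

    # masked sums; vectorized but algebraically the per-row OLS normal equations
    y = np.where(obs, beta, 0.0)
    x = np.where(obs, ages[None, :], 0.0)
    sum_x = x.sum(axis=1)
    sum_y = y.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = sum_x / n
        ybar = sum_y / n
        sxx = ((x - xbar[:, None]) ** 2 * obs).sum(axis=1)
        syy = ((y - ybar[:, None]) ** 2 * obs).sum(axis=1)
        sxy = ((x - xbar[:, None]) * (y - ybar[:, None]) * obs).sum(axis=1)

        usable = (n >= max(min_n, 3)) & (sxx > 0)
        slope = np.where(usable & (syy > 0), sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        intercept = ybar - slope * xbar
        r2 = np.where(
            usable & (syy > 0),
            sxy**2 / np.where((sxx > 0) & (syy > 0), sxx * syy, 1.0),
            0.0,
        )
    r2 = np.clip(r2, 0.0, 1.0)
    df = np.maximum(n - 2, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.sqrt(r2 * df / np.maximum(1.0 - r2, 1e-300))
    p = np.where(r2 >= 1.0, 0.0, 2.0 * stats.t.sf(t, df))
    p = np.where(usable & (syy > 0), np.minimum(p, 1.0), 1.0)

    rows: list[AgeRegressionRow] = []
    kept_idx: list[int] = []
    for i in range(len(m.sites)):
        if n[i] < max(min_n, 3) or sxx[i] <= 0:
            continue
        kept_idx.append(i)
    n_skipped = len(m.sites) - len(kept_idx)
    if n_skipped:
        log.info("fit_age_regression: skipped %d rows with n < %d or constant ages",
                 n_skipped, max(min_n, 3))

    qvals = np.ones(len(kept_idx))
    if kept_idx:
        qvals = stats.false_discovery_control(p[kept_idx], method="bh")
    for rank, i in enumerate(kept_idx):
        s = float(slope[i])
        if abs(s) <= flat_epsilon:
            direction = "flat"
        else:
            direction = "positive" if s > 0 else "negative"
        rows.append(
            AgeRegressionRow(
                site=m.sites[i],
                mod_code=m.mod_code,
                n=int(n[i]),
                slope=s,
                intercept=float(intercept[i]),
                r2=float(r2[i]),
                p=float(p[i]),
                q=float(qvals[rank]),
                direction=direction,
            )
        )
    return rows


def slope_p_from_r2(r2: float, n: int) -> float:
    """Two-sided p-value of the slope t-test implied by R² at sample size n.

    Deterministic closed form: with df = n-2 and t = sqrt(R² df / (1-R²)),
    p = 2 P(T_df >= t).  Strictly decreasing in both R² and n; R²=1 maps to
    the limit p=0.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must lie in [0, 1], got {r2}")
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    if r2 == 1.0:
        return 0.0
    df = n - 2
    t = np.sqrt(r2 * df / (1.0 - r2))
    return float(2.0 * stats.t.sf(t, df))


def filter_rows(
    rows: Sequence[AgeRegressionRow], min_r2: float = 0.8, max_p: float = 0.001
) -> list[AgeRegressionRow]:
    """Keep rows with R² >= min_r2 and p < max_p; order preserved."""
    if not (0.0 <= min_r2 <= 1.0) or not (0.0 < max_p <= 1.0):
        raise ValueError("thresholds out of range")
    return [r for r in rows if r.r2 >= min_r2 and r.p < max_p]


def top_by_slope(
    rows: Sequence[AgeRegressionRow], k: int, direction: str
) -> list[AgeRegressionRow]:
    """The k most age-correlated rows by slope.

    ``positive``: k largest slopes, descending; ``negative``: k smallest,
    ascending.  Slope ties break on (chrom, pos0) so output is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    sign = -1.0 if direction == "positive" else 1.0
    ordered = sorted(rows, key=lambda r: (sign * r.slope, r.site.chrom, r.site.pos0))
    if k > len(ordered):
        log.info("top_by_slope: requested %d rows, only %d available", k, len(ordered))
    return ordered[:k]


def direction_summary(
    rows: Sequence[AgeRegressionRow],
) -> tuple[float, float, float]:
    """(frac_negative, frac_positive, frac_flat).

    Negative/positive fractions are taken over non-flat rows (they sum to 1
    whenever any row is non-flat, matching how hypo/hyper percentages are
    reported); the flat fraction is over all rows.
    """
    if not rows:
        raise ValueError("direction_summary of empty row list")
    n_neg = sum(r.direction == "negative" for r in rows)
    n_pos = sum(r.direction == "positive" for r in rows)
    n_flat = len(rows) - n_neg - n_pos
    nonflat = n_neg + n_pos
    if nonflat == 0:
        log.warning("direction_summary: all slopes flat; directional fractions set to 0")
        return 0.0, 0.0, 1.0
    return n_neg / nonflat, n_pos / nonflat, n_flat / len(rows)


_SORT_KEYS = {
    "slope": lambda r: -abs(r.slope),
    "r2": lambda r: -r.r2,
    "p": lambda r: r.p,
}


def write_rows(
    rows: Sequence[AgeRegressionRow], path: str | Path, sort: str | None = None
) -> Path:
    """Write regression rows as a TSV report (both 0- and 1-based positions)."""
    path = Path(path)
    if sort is not None:
        if sort not in _SORT_KEYS:
            raise ValueError(f"sort must be one of {sorted(_SORT_KEYS)}")
        rows = sorted(rows, key=_SORT_KEYS[sort])
    with open(path, "w") as fh:
        fh.write("#site\tpos0\tpos1\tstrand\tmod_code\tn\tslope\tintercept\tr2\tp\tq\tdirection\n")
        for r in rows:
            fh.write(
                f"{r.site.chrom}_{r.site.pos1}\t{r.site.pos0}\t{r.site.pos1}\t{r.site.strand}\t"
                f"{r.mod_code}\t{r.n}\t{r.slope:.6g}\t{r.intercept:.6g}\t{r.r2:.6g}\t"
                f"{r.p:.6g}\t{r.q:.6g}\t{r.direction}\n"
            )
    return path
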