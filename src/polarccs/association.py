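"""Statistical analyses of CCS against physicochemical properties.

Four instruments of analysis:

* :func:`simple_linear_fit` — ordinary least squares with R² and a
  mean-response confidence band (99% by default).
* :func:`mlr_interaction` — the interaction regression

      CCS = mu + alpha*P + beta*X + gamma*(P*X) + eps,

  where ``P`` is the adduct polarizability and ``X`` is either m/z (mass
  effect) or ovality (shape effect), fitted as a Gaussian GLM with Wald
  tests per coefficient.  By default the fit is restricted to the m/z
  window [87.04, 385.35] Da where small-molecule datasets are densely
  populated.
* :func:`per_adduct_regressions` — separate lines per adduct type with a
  pairwise confidence-band overlap report (do the M+H / M+Na / M-H lines
  agree within each other's 99% bands?).
* :func:`build_heatmap` / :func:`conditional_trends` — bin the data on a
  property pair, average CCS per cell, then ask how CCS moves along one
  property while the other is held (binned) constant.  Within each row of
  the grid a count-weighted least-squares slope of cell-mean CCS on bin
  centers is computed; row slopes are pooled by inverse variance, using a
  pooled within-cell CCS variance, giving one slope, standard error and
  two-sided p-value per direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data_model import PropertyDataset, filter_by_mz_range

__all__ = [
    "LinearFitResult",
    "InteractionModelResult",
    "HeatmapGrid",
    "TrendResult",
    "RankDeficiencyError",
    "simple_linear_fit",
    "mlr_interaction",
    "per_adduct_regressions",
    "build_heatmap",
    "conditional_trends",
    "DEFAULT_MZ_WINDOW",
]

#: m/z window (Da, inclusive) where small-molecule tables are densest
DEFAULT_MZ_WINDOW: tuple[float, float] = (87.04, 385.35)


class RankDeficiencyError(ValueError):
    """The regression design matrix is rank-deficient (collinear columns)."""


@dataclass
class LinearFitResult:
    """OLS fit of y on x with a mean-response confidence band."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int
    confidence_level: float
    x_mean: float
    sxx: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def band_halfwidth(self, x):
        """Half-width of the mean-response confidence interval at x."""
        x = np.asarray(x, dtype=float)
        t_crit = stats.t.ppf(0.5 + self.confidence_level / 2.0, self.n - 2)
        return t_crit * self.residual_sd * np.sqrt(1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)

    def confidence_band(self, x):
        """(center, half_width) of the mean-response band at x."""
        return self.predict(x), self.band_halfwidth(x)


@dataclass
class InteractionModelResult:
    """Coefficients of CCS = mu + alpha*P + beta*X + gamma*P*X + eps."""

    mu: float
    alpha: float
    beta: float
    gamma: float
    se: dict[str, float]
    p_values: dict[str, float]
    covariate: str
    mz_window: tuple[float, float]
    n: int
    residual_sd: float

    def coefficients(self) -> dict[str, float]:
        return {"mu": self.mu, "alpha": self.alpha, "beta": self.beta, "gamma": self.gamma}

    def confidence_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        est = self.coefficients()[name]
        return est - z * self.se[name], est + z * self.se[name]


@dataclass
class HeatmapGrid:
    """CCS means binned over a property pair.

    ``mean``, ``count`` and ``var`` are (nx, ny) arrays indexed
    [x_bin, y_bin]; ``mask`` is True where the cell count is below
    ``min_count`` (those cells are ignored by the trend analysis).
    """

    var_x: str
    var_y: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    mean: np.ndarray
    count: np.ndarray
    var: np.ndarray
    min_count: int

    @property
    def mask(self) -> np.ndarray:
        return self.count < self.min_count

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def pooled_within_cell_variance(self) -> float:
        usable = (~self.mask) & (self.count >= 2)
        if not usable.any():
            return float("nan")
        dof = self.count[usable] - 1
        return float(np.sum(dof * self.var[usable]) / np.sum(dof))


@dataclass
class TrendResult:
    """Pooled slope of cell-mean CCS along one grid axis at fixed other axis."""

    direction: str  # e.g. "varying polarizability at fixed mz"
    slope: float
    se: float
    p_value: float
    cells_used: int
    transects_used: int


def simple_linear_fit(
    x: Sequence[float], y: Sequence[float], confidence_level: float = 0.99
) -> LinearFitResult:
    """OLS of y on x; R² = 1 - SSE/SST; normal-theory mean-response band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length x, y with n >= 3")
    if np.ptp(x) == 0:
        raise RankDeficiencyError("x is constant; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(res.ssr / (len(x) - 2)))
    return LinearFitResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        residual_sd=resid_sd,
        n=len(x),
        confidence_level=confidence_level,
        x_mean=float(np.mean(x)),
        sxx=float(np.sum((x - np.mean(x)) ** 2)),
    )


def mlr_interaction(
    ds: PropertyDataset,
    covariate: str = "mz",
    window: tuple[float, float] = DEFAULT_MZ_WINDOW,
) -> InteractionModelResult:
    """Interaction regression of CCS on polarizability and a second property.

    ``covariate`` is ``"mz"`` (mass effect) or ``"ovality"`` (shape
    effect).  Records outside the inclusive m/z ``window`` are excluded
    before fitting.  The fit is a Gaussian-family GLM — numerically ordinary
    least squares — with normal-theory Wald tests per coefficient.
    """
    if covariate not in ("mz", "ovality"):
        raise ValueError(f"covariate must be 'mz' or 'ovality', got {covariate!r}")
    sub = filter_by_mz_range(ds, window[0], window[1])
    if len(sub) < 5:
        raise ValueError(f"only {len(sub)} records in m/z window {window}; need >= 5")
    P = sub.feature_matrix(["polarizability"]).ravel()
    X = sub.feature_matrix([covariate]).ravel()
    y = sub.ccs_values()
    design = np.column_stack([np.ones_like(P), P, X, P * X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankDeficiencyError(
            f"design matrix [1, P, {covariate}, P*{covariate}] is rank-deficient"
        )
    model = sm.GLM(y, design, family=sm.families.Gaussian())
    res = model.fit()
    names = ("mu", "alpha", "beta", "gamma")
    se = {name: float(res.bse[i]) for i, name in enumerate(names)}
    pvals = {name: float(res.pvalues[i]) for i, name in enumerate(names)}
    resid_sd = float(np.sqrt(res.scale))
    return InteractionModelResult(
        mu=float(res.params[0]),
        alpha=float(res.params[1]),
        beta=float(res.params[2]),
        gamma=float(res.params[3]),
        se=se,
        p_values=pvals,
        covariate=covariate,
        mz_window=window,
        n=len(sub),
        residual_sd=resid_sd,
    )


def per_adduct_regressions(
    ds: PropertyDataset,
    x: str = "polarizability",
    y: str = "ccs",
    confidence_level: float = 0.99,
    n_probe: int = 25,
) -> tuple[dict[str, LinearFitResult], list[dict]]:
    """Independent OLS fits per adduct type, plus a band-overlap report.

    For every pair of adduct types the report states, over a probe grid of
    x values spanning the pair's shared range, the fraction of probe points
    at which each line lies inside the other's confidence band, and whether
    the two lines are mutually within bands at every probe point.
    Adduct types with fewer than 3 records are skipped with a warning.
    """
    fits: dict[str, LinearFitResult] = {}
    xdata: dict[str, np.ndarray] = {}
    for adduct in ("M+H", "M+Na", "M-H"):
        recs = [r for r in ds if r.adduct_type == adduct]
        if not recs:
            continue
        if len(recs) < 3:
            warnings.warn(f"adduct {adduct}: only {len(recs)} records; skipped")
            continue
        sub = PropertyDataset(records=recs)
        xv = sub.feature_matrix([x]).ravel()
        yv = sub.ccs_values() if y == "ccs" else sub.feature_matrix([y]).ravel()
        fits[adduct] = simple_linear_fit(xv, yv, confidence_level)
        xdata[adduct] = xv
    report: list[dict] = []
    for a, b in combinations(fits, 2):
        lo = max(xdata[a].min(), xdata[b].min())
        hi = min(xdata[a].max(), xdata[b].max())
        if not lo < hi:
            continue
        probe = np.linspace(lo, hi, n_probe)
        ca, ha = fits[a].confidence_band(probe)
        cb, hb = fits[b].confidence_band(probe)
        a_in_b = np.abs(ca - cb) <= hb
        b_in_a = np.abs(cb - ca) <= ha
        # both fits are noisy, so agreement is judged on the difference of
        # the two mean responses against its own band, sqrt(ha^2 + hb^2)
        agree = np.abs(ca - cb) <= np.hypot(ha, hb)
        report.append(
            {
                "pair": (a, b),
                "fraction_a_in_b_band": float(np.mean(a_in_b)),
                "fraction_b_in_a_band": float(np.mean(b_in_a)),
                "mutually_within_bands": bool(np.all(agree)),
            }
        )
    return fits, report


def build_heatmap(
    ds: PropertyDataset,
    var_x: str,
    var_y: str,
    bins: tuple[int, int] = (10, 10),
    min_count: int = 3,
) -> HeatmapGrid:
    """Bin records on (var_x, var_y) and average CCS per cell.

    Equal-width bins over the observed ranges; every record falls in exactly
    one cell.  Cells with fewer than ``min_count`` members are masked for
    the trend analysis.
    """
    if len(ds) < 1:
        raise ValueError("empty dataset")
    xv = ds.feature_matrix([var_x]).ravel()
    yv = ds.feature_matrix([var_y]).ravel()
    ccs = ds.ccs_values()
    nx, ny = bins
    mean, x_edges, y_edges, binnum = stats.binned_statistic_2d(
        xv, yv, ccs, statistic="mean", bins=[nx, ny]
    )
    count, _, _, _ = stats.binned_statistic_2d(xv, yv, ccs, statistic="count", bins=[x_edges, y_edges])

    def _cell_var(values):
        return np.var(values, ddof=1) if len(values) > 1 else np.nan

    var, _, _, _ = stats.binned_statistic_2d(xv, yv, ccs, statistic=_cell_var, bins=[x_edges, y_edges])
    count = count.astype(int)
    return HeatmapGrid(
        var_x=var_x,
        var_y=var_y,
        x_edges=x_edges,
        y_edges=y_edges,
        mean=mean,
        count=count,
        var=var,
        min_count=min_count,
    )


def _pooled_transect_slope(
    centers: np.ndarray, means: np.ndarray, counts: np.ndarray, mask: np.ndarray, sigma2: float
) -> tuple[float, float, int, int]:
    """Inverse-variance pooled slope over transects (rows of the arrays).

    ``means``/``counts``/``mask`` are (n_transects, n_cells); each transect
    with >= 2 unmasked cells contributes a count-weighted LS slope with
    variance ``sigma2 / sum_c n_c (x_c - xbar_w)^2``.
    Returns (slope, se, cells_used, transects_used); slope is nan when no
    transect is usable.
    """
    num = 0.0
    den = 0.0
    cells_used = 0
    transects = 0
    for t in range(means.shape[0]):
        usable = ~mask[t]
        if usable.sum() < 2:
            continue
        x = centers[usable]
        m = means[t, usable]
        w = counts[t, usable].astype(float)
        xbar = np.average(x, weights=w)
        sxx = np.sum(w * (x - xbar) ** 2)
        if sxx <= 0:
            continue
        slope_t = np.sum(w * (x - xbar) * m) / sxx
        var_t = sigma2 / sxx  # Var(cell mean) = sigma2 / n_c, weights n_c
        transects += 1
        cells_used += int(usable.sum())
        if var_t > 0:
            num += slope_t / var_t
            den += 1.0 / var_t
        else:  # degenerate: noiseless cells
            num += slope_t * 1e12
            den += 1e12
    if transects == 0:
        return float("nan"), float("nan"), 0, 0
    slope = num / den
    se = float(np.sqrt(1.0 / den))
    return float(slope), se, cells_used, transects


def conditional_trends(grid: HeatmapGrid) -> tuple[TrendResult, TrendResult]:
    """Trends of cell-mean CCS along each grid axis with the other fixed.

    Returns ``(along_x, along_y)``: ``along_x`` varies ``var_x`` within rows
    of fixed ``var_y`` (and vice versa).  Slopes are pooled across transects
    by inverse variance; p-values are two-sided normal-theory tests of zero
    slope.  Raises if neither direction has a transect with two usable
    cells.
    """
    sigma2 = grid.pooled_within_cell_variance()
    if not np.isfinite(sigma2):
        raise ValueError("no cell has enough members to estimate within-cell variance")
    mask = grid.mask

    results = []
    for direction, centers, means, counts, m in (
        (
            f"varying {grid.var_x} at fixed {grid.var_y}",
            grid.x_centers,
            grid.mean.T,
            grid.count.T,
            mask.T,
        ),
        (
            f"varying {grid.var_y} at fixed {grid.var_x}",
            grid.y_centers,
            grid.mean,
            grid.count,
            mask,
        ),
    ):
        slope, se, cells, transects = _pooled_transect_slope(centers, means, counts, m, sigma2)
        if transects == 0:
            results.append(
                TrendResult(direction=direction, slope=float("nan"), se=float("nan"),
                            p_value=float("nan"), cells_used=0, transects_used=0)
            )
            continue
        if se == 0.0:
            p = 1.0 if slope == 0.0 else 0.0
        else:
            p = float(2.0 * stats.norm.sf(abs(slope) / se))
        results.append(
            TrendResult(direction=direction, slope=slope, se=se, p_value=p,
                        cells_used=cells, transects_used=transects)
        )
    along_x, along_y = results
    if along_x.transects_used == 0 and along_y.transects_used == 0:
        raise ValueError("no direction has a transect with >= 2 usable cells")
    return along_x, along_y
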