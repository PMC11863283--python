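"""Between-method uncertainty analyses.

Given the same rings measured by several acquisition methods, this module
quantifies how well each method reproduces a reference (by convention the
high-resolution stained thin section, analysed with the lumen-area cut-off):

* **pairwise regression** of the annual time series of each ring parameter
  (MLA, VD, VN, D_h, RCA): ordinary least squares of the compared method on
  the reference, reporting R², slope, intercept, slope p-value, and the
  relative offset from the 1:1 line (mean per-year relative difference, %);
* **lumen-area distributions**: normalised histogram densities on a
  log-area grid, the summary in which diffuse-porous anatomy shows a single
  right-skewed mode and ring-porous anatomy two modes;
* **aggregated radial profiles** of K_s and ρ on a common relative-position
  axis (0–100 % of ring width), fitted per method with a two-stage
  smoother: per-year means are removed first (absorbing the year-level
  intercept), then a cubic B-spline regression with the knot count chosen
  by generalized cross-validation; pointwise confidence bands come from a
  year-blocked bootstrap.  Grid positions where a method's band excludes
  the reference mean are flagged as significant differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .core_data import RunConfig, SampleTable
from .errors import ConfigError, InsufficientDataError
from .ring_metrics import compute_ring_metrics

RING_PARAMETERS = ("mla", "vd", "vn", "dh", "rca")
REFERENCE_METHOD = "thin_section"
FULL_VARIANT_METHOD = "thin_section_full"


@dataclass(frozen=True)
class ComparisonResult:
    """Regression statistics for one parameter and one method pair."""

    parameter: str
    reference: str
    compared: str
    n_years: int
    r2: float
    slope: float
    intercept: float
    offset_pct: float  # mean relative offset from the 1:1 line, %
    offset_resid_pct: float  # mean relative residual from the fitted line, %
    p_slope: float
    n_zero_ref_excluded: int


@dataclass
class ProfileFit:
    """Smoothed radial profile of one parameter for one method."""

    parameter: str
    method: str
    grid: np.ndarray  # rel_position, %
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_years: int
    low_confidence: bool = False


def pairwise_regression(
    ref: pd.Series,
    cmp: pd.Series,
    parameter: str = "",
    reference: str = REFERENCE_METHOD,
    compared: str = "",
) -> ComparisonResult:
    """OLS of the compared method's annual series on the reference's.

    Series are aligned on their index (year) and reduced to pairwise
    complete observations; at least 3 shared years are required.  The
    offset from the 1:1 line is ``100 × mean((cmp − ref)/ref)`` over years
    with non-zero reference; zero-reference years are excluded and counted.
    """
    joined = pd.concat({"ref": ref, "cmp": cmp}, axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise InsufficientDataError(
            f"pairwise regression needs >= 3 shared years, got {n}"
        )
    x = joined["ref"].to_numpy(dtype=float)
    y = joined["cmp"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    nonzero = x != 0
    rel = (y[nonzero] - x[nonzero]) / x[nonzero]
    fitted = fit.intercept + fit.slope * x
    rel_resid = (y[nonzero] - fitted[nonzero]) / x[nonzero]
    return ComparisonResult(
        parameter=parameter,
        reference=reference,
        compared=compared,
        n_years=n,
        r2=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        offset_pct=float(100.0 * rel.mean()) if nonzero.any() else float("nan"),
        offset_resid_pct=float(100.0 * rel_resid.mean()) if nonzero.any() else float("nan"),
        p_slope=float(fit.pvalue),
        n_zero_ref_excluded=int((~nonzero).sum()),
    )


def offset_bootstrap_ci(
    ref: pd.Series,
    cmp: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Year-blocked bootstrap percentile CI of the 1:1-line offset (%).

    Years are resampled with replacement; the offset is recomputed on each
    resample.
    """
    joined = pd.concat({"ref": ref, "cmp": cmp}, axis=1, join="inner").dropna()
    joined = joined[joined["ref"] != 0]
    rel = 100.0 * (joined["cmp"] - joined["ref"]) / joined["ref"]
    rel = rel.to_numpy(dtype=float)
    if rel.size < 2:
        raise InsufficientDataError("bootstrap CI needs >= 2 usable years")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rel.size, size=(n_boot, rel.size))
    means = rel[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def metrics_by_method(
    tables: dict[str, SampleTable], config: RunConfig
) -> dict[str, pd.DataFrame]:
    """Per-ring metrics for every method table.

    Every method is analysed with the configured cut-off except the
    fibres-included thin-section variant, which keeps all detected
    elements.
    """
    out = {}
    for method, table in tables.items():
        use_cutoff = method != FULL_VARIANT_METHOD
        out[method] = compute_ring_metrics(table, config, use_cutoff=use_cutoff)
    return out


def compare_all(
    tables: dict[str, SampleTable],
    config: RunConfig,
    reference: str = REFERENCE_METHOD,
) -> pd.DataFrame:
    """All parameter × method-pair regressions against the reference method.

    Returns one row per (parameter, compared method) with the
    :class:`ComparisonResult` fields as columns.
    """
    if reference not in tables:
        raise ConfigError(f"reference method {reference!r} missing from tables")
    metrics = metrics_by_method(tables, config)
    ref_metrics = metrics[reference].set_index("year")
    rows = []
    for method, frame in metrics.items():
        if method == reference:
            continue
        cmp_metrics = frame.set_index("year")
        for parameter in RING_PARAMETERS:
            result = pairwise_regression(
                ref_metrics[parameter],
                cmp_metrics[parameter],
                parameter=parameter,
                reference=reference,
                compared=method,
            )
            rows.append(result.__dict__)
    return pd.DataFrame(rows)


def lumen_distribution(
    table: SampleTable,
    config: RunConfig | None = None,
    cutoff: float | None = None,
    n_bins: int = 60,
) -> pd.DataFrame:
    """Histogram density of cell lumen area across all rings, on a log grid.

    The density is normalised to integrate to 1 over log10(area), so shapes
    are comparable across methods regardless of detected-cell counts.
    Returns columns ``log10_area, area_um2, density``; empty for an empty
    table.
    """
    areas = table.cells["lumen_area_um2"].to_numpy(dtype=float)
    if cutoff is not None:
        areas = areas[areas > cutoff]
    if areas.size == 0:
        return pd.DataFrame(columns=["log10_area", "area_um2", "density"])
    log_a = np.log10(areas)
    density, edges = np.histogram(log_a, bins=n_bins, density=True)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return pd.DataFrame(
        {"log10_area": centers, "area_um2": 10.0**centers, "density": density}
    )


def aggregate_profiles(
    series: dict[str, pd.DataFrame] | pd.DataFrame,
    parameter: str,
) -> pd.DataFrame:
    """Stack sector series onto a common relative-position axis.

    ``series`` is a sector-series DataFrame (from
    :func:`qwamap.sector_profile.build_sector_series`) or a mapping of
    method label to such a frame.  Returns long format
    ``method, year, rel_position, value`` with years kept separate so the
    smoother can honour year-level grouping; rows with missing values
    (e.g. the median of an empty sector) are dropped.
    """
    if isinstance(series, pd.DataFrame):
        frames = {"single": series}
    else:
        frames = series
    out = []
    for method, frame in frames.items():
        if parameter not in frame.columns:
            raise ConfigError(f"parameter {parameter!r} not present in sector series")
        sub = frame[["year", "rel_position", parameter]].rename(columns={parameter: "value"})
        sub.insert(0, "method", method)
        out.append(sub)
    result = pd.concat(out, ignore_index=True)
    return result.dropna(subset=["value"]).reset_index(drop=True)


def _spline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cubic B-spline design matrix on [0, 100] with given interior knots."""
    t = np.concatenate([[0.0] * 4, knots, [100.0] * 4])
    xc = np.clip(x, 0.0, 100.0 - 1e-9)
    return BSpline.design_matrix(xc, t, 3).toarray()


def _fit_spline(
    x: np.ndarray, v: np.ndarray, knot_grid: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares cubic spline with GCV-selected interior knot count.

    Returns (interior knots, coefficients).  Knots are placed at quantiles
    of the observed positions.  GCV score: ``n·RSS / (n − p)²`` with p the
    number of basis functions (unpenalised fit).
    """
    best = None
    for n_knots in knot_grid:
        if n_knots > 0:
            qs = np.linspace(0, 1, n_knots + 2)[1:-1]
            knots = np.unique(np.quantile(x, qs))
        else:
            knots = np.array([])
        p = 4 + len(knots)
        if len(x) <= p + 1:
            continue
        X = _spline_design(x, knots)
        coef, *_ = np.linalg.lstsq(X, v, rcond=None)
        rss = float(np.sum((v - X @ coef) ** 2))
        gcv = len(x) * rss / (len(x) - p) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, knots, coef)
    if best is None:
        raise InsufficientDataError("too few sector observations for the profile smoother")
    return best[1], best[2]


def fit_profile(
    aggregated: pd.DataFrame,
    parameter: str = "",
    reference: str | None = None,
    grid_n: int = 41,
    knot_grid: tuple[int, ...] = (0, 1, 2, 3, 4, 6, 8),
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[dict[str, ProfileFit], pd.DataFrame]:
    """Smoothed mean radial profile with confidence bands, per method.

    The year-level intercept is absorbed by centring each year's values on
    the method's grand mean before the spline fit; pointwise bands come
    from resampling whole years with replacement (percentile method,
    ``n_boot`` resamples).  With a single year, bands fall back to the
    OLS prediction standard error and the fit is flagged low-confidence.

    Returns ``(fits, flags)``: a mapping of method to :class:`ProfileFit`,
    and a frame flagging grid positions where a method's band excludes the
    reference method's fitted mean (empty if no reference given).
    """
    grid = np.linspace(0.0, 100.0, grid_n)
    rng = np.random.default_rng(seed)
    fits: dict[str, ProfileFit] = {}
    for method, sub in aggregated.groupby("method", sort=True):
        x = sub["rel_position"].to_numpy(dtype=float)
        v = sub["value"].to_numpy(dtype=float)
        years = sub["year"].to_numpy()
        grand = v.mean()
        year_means = pd.Series(v).groupby(years).transform("mean").to_numpy()
        centred = v - year_means + grand
        knots, coef = _fit_spline(x, centred, knot_grid)
        Xg = _spline_design(grid, knots)
        mean = Xg @ coef
        uniq = np.unique(years)
        if len(uniq) >= 2:
            boot = np.empty((n_boot, grid_n))
            year_rows = {y: np.flatnonzero(years == y) for y in uniq}
            for b in range(n_boot):
                pick = rng.choice(uniq, size=len(uniq), replace=True)
                rows = np.concatenate([year_rows[y] for y in pick])
                Xb = _spline_design(x[rows], knots)
                cb, *_ = np.linalg.lstsq(Xb, centred[rows], rcond=None)
                boot[b] = Xg @ cb
            lower = np.quantile(boot, alpha / 2.0, axis=0)
            upper = np.quantile(boot, 1.0 - alpha / 2.0, axis=0)
            low_confidence = False
        else:
            X = _spline_design(x, knots)
            resid = centred - X @ coef
            dof = max(len(x) - X.shape[1], 1)
            sigma2 = float(resid @ resid) / dof
            cov = sigma2 * np.linalg.pinv(X.T @ X)
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov, Xg), 0.0))
            z = stats.norm.ppf(1.0 - alpha / 2.0)
            lower, upper = mean - z * se, mean + z * se
            low_confidence = True
        # percentile bands can sit fractionally inside the point estimate;
        # widen so they always bracket it
        lower = np.minimum(lower, mean)
        upper = np.maximum(upper, mean)
        fits[method] = ProfileFit(
            parameter=parameter,
            method=str(method),
            grid=grid,
            mean=mean,
            lower=lower,
            upper=upper,
            n_years=len(uniq),
            low_confidence=low_confidence,
        )
    flag_rows = []
    if reference is not None and reference in fits:
        ref_mean = fits[reference].mean
        for method, fit in fits.items():
            if method == reference:
                continue
            differs = (fit.lower > ref_mean) | (fit.upper < ref_mean)
            for g, d in zip(grid, differs):
                flag_rows.append(
                    {"method": method, "rel_position": float(g), "differs": bool(d)}
                )
    flags = pd.DataFrame(flag_rows, columns=["method", "rel_position", "differs"])
    return fits, flags
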