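"""Developmental trends in association strength.

The per-wave adjusted-R2 gain of a score is modelled as a smooth
function of the mean participant age at measurement.  The smooth is a
natural cubic regression spline with 3 degrees of freedom when more than
3 time points exist, otherwise 2.  Significance is decomposed by nested
F-ratios: the parametric (linear) component compares the linear fit to
the intercept-only fit, the non-parametric component compares the spline
to the linear fit.  Confidence bands come from resampling individuals
with replacement and recomputing the per-wave adjusted-R2 values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from prsphewas.genio import GenotypeMatrix, WeightSet
from prsphewas.phewas import PhenotypeTable, PhewasError, fit_linear_assoc
from prsphewas.scoring import compute_prs, standardize

__all__ = ["TrendSeries", "TrendResult", "fit_trend", "bootstrap_trend"]

GRID_POINTS = 100


class TrendError(ValueError):
    pass


@dataclass
class TrendSeries:
    """Per-wave (mean_age, delta_adj_r2 percent) points for one score/phenotype."""

    prs_name: str
    phenotype: str
    points: pd.DataFrame  # mean_age, delta_adj_r2, n, wave

    def __post_init__(self) -> None:
        for col in ("mean_age", "delta_adj_r2"):
            if col not in self.points.columns:
                raise TrendError(f"trend points missing column {col!r}")
        self.points = self.points.sort_values("mean_age").reset_index(drop=True)
        ages = self.points["mean_age"].to_numpy()
        if np.unique(ages).size != ages.size:
            raise TrendError("duplicate mean ages in trend series")


@dataclass
class TrendResult:
    prs_name: str
    phenotype: str
    df_used: int  # 1 = linear-only fallback
    grid_age: np.ndarray
    fit: np.ndarray
    lo95: np.ndarray | None = None
    hi95: np.ndarray | None = None
    slope: float = np.nan
    f_linear: float = np.nan
    p_linear: float = np.nan
    f_nonlinear: float = np.nan
    p_nonlinear: float = np.nan
    rss: dict = field(default_factory=dict)
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prs_name": self.prs_name,
                "phenotype": self.phenotype,
                "age": self.grid_age,
                "fit": self.fit,
                "lo95": self.lo95 if self.lo95 is not None else np.nan,
                "hi95": self.hi95 if self.hi95 is not None else np.nan,
            }
        )


def _natural_spline_knots(ages: np.ndarray, df: int) -> np.ndarray:
    """df+1 knots at equally spaced quantiles of the observed ages."""
    qs = np.linspace(0.0, 1.0, df + 1)
    knots = np.quantile(ages, qs)
    if np.unique(knots).size != knots.size:
        raise TrendError("degenerate knot sequence (tied ages)")
    return knots


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    Truncated-power construction: columns are x and
    ``N_k(x) = d_k(x) - d_{K-1}(x)`` for k = 1..K-2 with
    ``d_k(x) = ((x-xi_k)_+^3 - (x-xi_K)_+^3) / (xi_K - xi_k)``, giving
    K-1 columns (excluding the intercept) for K knots.  The span
    contains every linear function, so the linear model is nested.
    """
    K = knots.size
    xK, xKm1 = knots[-1], knots[-2]

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - xK, 0, None) ** 3
        return num / (xK - knots[k])

    dKm1 = d(K - 2)
    cols = [x] + [d(k) - dKm1 for k in range(K - 2)]
    return np.column_stack(cols)


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def choose_df(n_points: int) -> int:
    """3 df for more than 3 time points, 2 df for exactly 3, else linear-only."""
    if n_points > 3:
        return 3
    if n_points == 3:
        return 2
    return 1


def fit_trend(ts: TrendSeries) -> TrendResult:
    """Nested intercept / linear / spline fits with F-ratio decomposition.

    With fewer than 3 points only the linear component is fitted and
    ``p_nonlinear`` is NaN; fewer than 2 points is an error.  When the
    spline saturates the points (zero residual df) the non-linear p-value
    is NaN while its F statistic is still reported.
    """
    ages = ts.points["mean_age"].to_numpy(dtype=float)
    y = ts.points["delta_adj_r2"].to_numpy(dtype=float)
    n = ages.size
    if n < 2:
        raise TrendError(f"{ts.prs_name}/{ts.phenotype}: need >= 2 time points, got {n}")
    grid = np.linspace(ages.min(), ages.max(), GRID_POINTS)
    ones = np.ones((n, 1))
    _, rss0 = _rss(y, ones)
    beta1, rss1 = _rss(y, np.hstack([ones, ages[:, None]]))
    df_used = choose_df(n)
    result = TrendResult(
        prs_name=ts.prs_name,
        phenotype=ts.phenotype,
        df_used=df_used,
        grid_age=grid,
        fit=beta1[0] + beta1[1] * grid,
        slope=float(beta1[1]),
        rss={"intercept": rss0, "linear": rss1},
    )
    # parametric (linear) component: linear vs intercept-only
    if n > 2 and rss1 > 0:
        f_lin = (rss0 - rss1) / (rss1 / (n - 2))
        result.f_linear = max(0.0, float(f_lin))
        result.p_linear = float(stats.f.sf(result.f_linear, 1, n - 2))
    elif n == 2:
        result.f_linear = np.nan
        result.p_linear = np.nan
    if df_used == 1:
        return result
    knots = _natural_spline_knots(ages, df_used)
    basis = _natural_spline_basis(ages, knots)
    X2 = np.hstack([ones, basis])
    beta2, rss2 = _rss(y, X2)
    rss2 = min(rss2, rss1)  # nesting: spline space contains the linear fit
    result.rss["smooth"] = rss2
    grid_basis = _natural_spline_basis(grid, knots)
    result.fit = beta2[0] + grid_basis @ beta2[1:]
    # non-parametric component: spline vs linear
    df_num = df_used - 1
    df_den = n - 1 - df_used
    if rss2 > 0 and df_den > 0:
        f_nl = ((rss1 - rss2) / df_num) / (rss2 / df_den)
        result.f_nonlinear = max(0.0, float(f_nl))
        result.p_nonlinear = float(stats.f.sf(result.f_nonlinear, df_num, df_den))
    else:
        result.f_nonlinear = np.nan if rss2 <= 0 else max(0.0, float(rss1 - rss2))
        result.p_nonlinear = np.nan
    return result


def trend_series_from_results(results: pd.DataFrame, prs_name: str, phenotype: str) -> TrendSeries:
    """Build a TrendSeries from an association-scan result frame."""
    sub = results[(results["prs_name"] == prs_name) & (results["phenotype"] == phenotype)]
    if sub.empty:
        raise TrendError(f"no scan results for {prs_name}/{phenotype}")
    pts = sub[["mean_age", "delta_adj_r2_pct", "n", "wave"]].rename(
        columns={"delta_adj_r2_pct": "delta_adj_r2"}
    )
    return TrendSeries(prs_name, phenotype, pts)


def _wave_arrays(
    g: GenotypeMatrix, pt: PhenotypeTable, phenotype: str, waves: list
) -> tuple[list[dict], np.ndarray]:
    """Per-wave y/age vectors plus the covariate matrix, aligned to g.samples."""
    order = pd.DataFrame({"sample_id": g.samples})
    cov_df = order.merge(pt.samples, on="sample_id", how="left")
    cov_cols = ["sex", *pt.pc_columns]
    cov = cov_df[cov_cols].to_numpy(dtype=float)
    use_age = not pt.is_age_of_initiation(phenotype)
    out = []
    for wave in waves:
        meas = pt.measurements[
            (pt.measurements["phenotype"] == phenotype) & (pt.measurements["wave"] == wave)
        ]
        m = order.merge(meas[["sample_id", "age", "value"]], on="sample_id", how="left")
        out.append(
            {
                "wave": wave,
                "y": m["value"].to_numpy(dtype=float),
                "age": m["age"].to_numpy(dtype=float),
                "mean_age": float(m["age"].mean()),
                "use_age": use_age,
            }
        )
    return out, cov


def _wave_deltas(raw: np.ndarray, waves: list[dict], cov: np.ndarray, idx: np.ndarray) -> list[float]:
    r = raw[idx]
    sd = r.std(ddof=1)
    if sd == 0.0:
        raise PhewasError("degenerate resample: zero score variance")
    s = (r - r.mean()) / sd
    deltas = []
    for w in waves:
        cols = [cov[idx]]
        if w["use_age"]:
            cols.insert(0, w["age"][idx][:, None])
        res = fit_linear_assoc(w["y"][idx], s, np.hstack(cols))
        deltas.append(res.delta_adj_r2)
    return deltas


def bootstrap_trend(
    g: GenotypeMatrix,
    w: WeightSet,
    pt: PhenotypeTable,
    phenotype: str,
    B: int = 500,
    seed: int = 0,
    waves: list | None = None,
    missing_policy: str = "mean_impute",
    max_redraws: int = 100,
) -> TrendResult:
    """Individual-level bootstrap of the age trend for one score/phenotype.

    Each of the ``B`` resamples draws individuals with replacement,
    re-standardizes the raw score within the resample, recomputes the
    per-wave adjusted-R2 gain and refits the trend; the band is the
    2.5/97.5 percentile envelope on the age grid.  Degenerate resamples
    (zero score variance) are redrawn and counted in ``n_redrawn``.
    """
    if B < 100:
        warnings.warn(f"B={B} < 100 bootstrap resamples; bands will be noisy")
    if waves is None:
        pw = pt.phenotype_waves()
        waves = pw.loc[pw["phenotype"] == phenotype].sort_values("mean_age")["wave"].tolist()
    if len(waves) < 2:
        raise TrendError(f"{phenotype}: need >= 2 waves for a trend, got {len(waves)}")
    sv = compute_prs(g, w, missing_policy=missing_policy)
    raw = sv.raw
    wave_data, cov = _wave_arrays(g, pt, phenotype, waves)
    n = raw.size
    full_idx = np.arange(n)
    point_deltas = _wave_deltas(raw, wave_data, cov, full_idx)
    mean_ages = [wd["mean_age"] for wd in wave_data]
    base = fit_trend(
        TrendSeries(
            w.prs_name,
            phenotype,
            pd.DataFrame({"mean_age": mean_ages, "delta_adj_r2": point_deltas, "wave": waves}),
        )
    )
    rng = np.random.default_rng(seed)
    curves = np.empty((B, base.grid_age.size))
    redrawn = 0
    for b in range(B):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, n, n)
            try:
                deltas = _wave_deltas(raw, wave_data, cov, idx)
                break
            except PhewasError:
                redrawn += 1
        else:
            raise TrendError(f"bootstrap resample {b} degenerate after {max_redraws} redraws")
        fit_b = fit_trend(
            TrendSeries(
                w.prs_name,
                phenotype,
                pd.DataFrame({"mean_age": mean_ages, "delta_adj_r2": deltas, "wave": waves}),
            )
        )
        curves[b] = fit_b.fit
    # clamp so the band always contains the point prediction
    base.lo95 = np.minimum(np.percentile(curves, 2.5, axis=0), base.fit)
    base.hi95 = np.maximum(np.percentile(curves, 97.5, axis=0), base.fit)
    base.n_redrawn = redrawn
    return base
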