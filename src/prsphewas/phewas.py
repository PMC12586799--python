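"""Phenome-wide association scan with adjusted-R2 effect sizes.

Each standardized score is regressed against each phenotype/wave with a
linear model adjusting for sex, age at measurement (dropped for
age-of-initiation phenotypes) and 10 principal components.  Effect size
is the difference in adjusted R2 between the full and covariate-only
models, reported on the percent scale.  Benjamini-Hochberg correction is
applied within each score's family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from prsphewas.scoring import ScoreVector

__all__ = [
    "PhenotypeTable",
    "AssociationResult",
    "fit_linear_assoc",
    "bh_adjust",
    "run_phewas",
    "validate_prs",
    "compare_runs",
    "DEFAULT_PC_COLUMNS",
]

DEFAULT_PC_COLUMNS = tuple(f"pc{i}" for i in range(1, 11))


class PhewasError(ValueError):
    pass


@dataclass
class PhenotypeTable:
    """Sample covariates plus long-format phenotype measurements.

    ``samples``: one row per sample with ``sample_id``, ``sex`` (0/1) and
    PC columns.  ``measurements``: one row per sample per phenotype per
    wave with ``sample_id``, ``phenotype``, ``wave``, ``age``, ``value``.
    ``meta``: one row per phenotype with ``category`` and
    ``is_age_of_initiation``.
    """

    samples: pd.DataFrame
    measurements: pd.DataFrame
    meta: pd.DataFrame
    pc_columns: tuple[str, ...] = DEFAULT_PC_COLUMNS

    def __post_init__(self) -> None:
        for col in ("sample_id", "sex", *self.pc_columns):
            if col not in self.samples.columns:
                raise PhewasError(f"samples table missing column {col!r}")
        for col in ("sample_id", "phenotype", "wave", "age", "value"):
            if col not in self.measurements.columns:
                raise PhewasError(f"measurements table missing column {col!r}")
        for col in ("phenotype", "category", "is_age_of_initiation"):
            if col not in self.meta.columns:
                raise PhewasError(f"meta table missing column {col!r}")
        if self.samples["sample_id"].duplicated().any():
            raise PhewasError("duplicate sample ids in samples table")
        dup = self.measurements.duplicated(["sample_id", "phenotype", "wave"])
        if dup.any():
            raise PhewasError("duplicate (sample, phenotype, wave) measurement rows")
        ages = self.measurements["age"].dropna()
        if (ages <= 0).any():
            raise PhewasError("non-positive ages in measurements")

    def phenotype_waves(self) -> pd.DataFrame:
        """Unique (phenotype, wave) pairs with mean participant age and n."""
        grp = (
            self.measurements.groupby(["phenotype", "wave"], sort=True)
            .agg(mean_age=("age", "mean"), n=("value", "count"))
            .reset_index()
        )
        return grp

    def is_age_of_initiation(self, phenotype: str) -> bool:
        row = self.meta.loc[self.meta["phenotype"] == phenotype]
        if row.empty:
            return False
        return bool(row["is_age_of_initiation"].iloc[0])

    def category_of(self, phenotype: str) -> str | None:
        row = self.meta.loc[self.meta["phenotype"] == phenotype]
        return None if row.empty else str(row["category"].iloc[0])

    @classmethod
    def from_tsvs(
        cls, samples_path: str | Path, measurements_path: str | Path, meta_path: str | Path
    ) -> "PhenotypeTable":
        return cls(
            samples=pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str}),
            measurements=pd.read_csv(measurements_path, sep="\t", dtype={"sample_id": str}),
            meta=pd.read_csv(meta_path, sep="\t"),
        )


@dataclass
class AssociationResult:
    prs_name: str
    phenotype: str
    wave: str
    n: int
    beta: float
    se: float
    p: float
    q: float = np.nan
    delta_adj_r2: float = np.nan  # percent scale
    mean_age: float = np.nan
    significant: bool = False

    def to_dict(self) -> dict:
        return {
            "prs_name": self.prs_name,
            "phenotype": self.phenotype,
            "wave": self.wave,
            "n": self.n,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "q": self.q,
            "delta_adj_r2_pct": self.delta_adj_r2,
            "mean_age": self.mean_age,
            "significant": self.significant,
        }


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """OLS via pseudo-inverse; returns (beta, se, rss, df_resid).

    Raises on rank deficiency so collinear designs surface as errors
    rather than silently dropped columns.
    """
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise PhewasError(f"singular fit: design has rank {rank} < {k} columns")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - k
    if df_resid <= 0:
        raise PhewasError(f"non-positive residual df ({df_resid})")
    sigma2 = rss / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    return beta, se, rss, df_resid


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """1 - (1 - R2)(n - 1)/(n - k - 1), k = non-intercept predictors."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def fit_linear_assoc(
    y: np.ndarray,
    s: np.ndarray,
    cov: np.ndarray | None = None,
    prs_name: str = "prs",
    phenotype: str = "phenotype",
    wave: str = "w1",
) -> AssociationResult:
    """OLS of y on [intercept, score, covariates]; score inference + delta adj-R2.

    ``delta_adj_r2`` (percent) is adjR2(full) - adjR2(covariates only).
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if cov is None:
        cov = np.empty((y.size, 0))
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if not (y.size == s.size == cov.shape[0]):
        raise PhewasError("y, s and cov have inconsistent lengths")
    ok = np.isfinite(y) & np.isfinite(s) & np.all(np.isfinite(cov), axis=1)
    y, s, cov = y[ok], s[ok], cov[ok]
    n = y.size
    k_full = 1 + cov.shape[1]
    if n < k_full + 3:
        raise PhewasError(f"too few complete cases (n={n}) for {k_full} predictors")
    if np.var(y) == 0.0:
        raise PhewasError(f"phenotype {phenotype} has zero variance")
    ones = np.ones((n, 1))
    X_full = np.hstack([ones, s[:, None], cov])
    beta, se, rss_full, df_resid = _ols(y, X_full)
    tss = float(((y - y.mean()) ** 2).sum())
    r2_full = 1.0 - rss_full / tss
    if cov.shape[1]:
        _, _, rss_cov, _ = _ols(y, np.hstack([ones, cov]))
        r2_cov = 1.0 - rss_cov / tss
    else:
        r2_cov = 0.0
    delta = adjusted_r2(r2_full, n, k_full) - adjusted_r2(r2_cov, n, cov.shape[1])
    t_stat = beta[1] / se[1] if se[1] > 0 else np.inf * np.sign(beta[1])
    p = float(2.0 * stats.t.sf(abs(t_stat), df_resid))
    return AssociationResult(
        prs_name=prs_name,
        phenotype=phenotype,
        wave=wave,
        n=n,
        beta=float(beta[1]),
        se=float(se[1]),
        p=p,
        delta_adj_r2=100.0 * delta,
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise PhewasError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_phewas(
    scores: Sequence[ScoreVector],
    pt: PhenotypeTable,
    alpha: float = 0.05,
    family: str = "per_prs",
) -> pd.DataFrame:
    """Fit every score x phenotype x wave pair; BH within each score's family.

    Phenotypes flagged ``is_age_of_initiation`` omit the age covariate.
    Phenotype/waves whose fit fails (all missing, degenerate) are skipped
    and listed in the returned frame's ``attrs['skipped']``.
    """
    if family != "per_prs":
        raise PhewasError(f"unsupported family definition {family!r}")
    if not scores:
        raise PhewasError("no scores supplied")
    pairs = pt.phenotype_waves()
    if pairs.empty:
        raise PhewasError("no phenotype measurements")
    results: list[AssociationResult] = []
    skipped: list[dict] = []
    for sv in scores:
        if sv.standardized is None:
            raise PhewasError(f"score {sv.prs_name} is not standardized")
        sdf = pd.DataFrame({"sample_id": sv.samples, "_score": sv.standardized})
        base = pt.samples.merge(sdf, on="sample_id", how="inner")
        fam: list[AssociationResult] = []
        for row in pairs.itertuples(index=False):
            meas = pt.measurements[
                (pt.measurements["phenotype"] == row.phenotype)
                & (pt.measurements["wave"] == row.wave)
            ]
            df = base.merge(meas[["sample_id", "age", "value"]], on="sample_id", how="inner")
            df = df.dropna(subset=["value", "_score", "sex", *pt.pc_columns])
            cov_cols = ["sex", *pt.pc_columns]
            if not pt.is_age_of_initiation(row.phenotype):
                cov_cols.insert(1, "age")
                df = df.dropna(subset=["age"])
            try:
                res = fit_linear_assoc(
                    df["value"].to_numpy(),
                    df["_score"].to_numpy(),
                    df[cov_cols].to_numpy(),
                    prs_name=sv.prs_name,
                    phenotype=str(row.phenotype),
                    wave=str(row.wave),
                )
            except PhewasError as exc:
                skipped.append(
                    {"prs_name": sv.prs_name, "phenotype": row.phenotype, "wave": row.wave, "reason": str(exc)}
                )
                continue
            res.mean_age = float(row.mean_age)
            fam.append(res)
        if fam:
            qs = bh_adjust([r.p for r in fam])
            for r, q in zip(fam, qs):
                r.q = float(q)
                r.significant = bool(q < alpha)
            results.extend(fam)
    out = pd.DataFrame([r.to_dict() for r in results])
    out.attrs["skipped"] = skipped
    return out


def validate_prs(
    scores: Sequence[ScoreVector],
    pt: PhenotypeTable,
    validation_map: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One validation association per score, BH across the score set.

    ``validation_map`` assigns each score name its validation phenotype
    (earliest wave used when several exist).  Scores with q < alpha are
    flagged ``retained``.
    """
    rows: list[AssociationResult] = []
    for sv in scores:
        phen = validation_map.get(sv.prs_name)
        if phen is None:
            raise PhewasError(f"score {sv.prs_name} has no validation phenotype")
        waves = pt.phenotype_waves()
        sel = waves[waves["phenotype"] == phen].sort_values("mean_age")
        if sel.empty:
            raise PhewasError(f"validation phenotype {phen!r} not found for {sv.prs_name}")
        wave = sel["wave"].iloc[0]
        sdf = pd.DataFrame({"sample_id": sv.samples, "_score": sv.standardized})
        base = pt.samples.merge(sdf, on="sample_id", how="inner")
        meas = pt.measurements[
            (pt.measurements["phenotype"] == phen) & (pt.measurements["wave"] == wave)
        ]
        df = base.merge(meas[["sample_id", "age", "value"]], on="sample_id", how="inner")
        cov_cols = ["sex", *pt.pc_columns]
        if not pt.is_age_of_initiation(phen):
            cov_cols.insert(1, "age")
        df = df.dropna(subset=["value", "_score", *cov_cols])
        rows.append(
            fit_linear_assoc(
                df["value"].to_numpy(),
                df["_score"].to_numpy(),
                df[cov_cols].to_numpy(),
                prs_name=sv.prs_name,
                phenotype=phen,
                wave=str(wave),
            )
        )
    qs = bh_adjust([r.p for r in rows])
    out = pd.DataFrame([r.to_dict() for r in rows])
    out["q"] = qs
    out["retained"] = out["q"] < alpha
    return out


def compare_runs(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Regress run b's betas on run a's over shared (prs, phenotype, wave) keys.

    Returns slope, intercept, r2 of the fit plus the fraction of b's 95%
    CIs that cover a's point estimates (the sensitivity-run overlap check).
    """
    keys = ["prs_name", "phenotype", "wave"]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise PhewasError(f"only {len(merged)} shared keys; need >= 3 to compare runs")
    x = merged["beta_a"].to_numpy()
    y = merged["beta_b"].to_numpy()
    fit = stats.linregress(x, y)
    lo = merged["beta_b"] - 1.96 * merged["se_b"]
    hi = merged["beta_b"] + 1.96 * merged["se_b"]
    overlap = float(((merged["beta_a"] >= lo) & (merged["beta_a"] <= hi)).mean())
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "n_shared": int(len(merged)),
        "ci_overlap_fraction": overlap,
    }
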