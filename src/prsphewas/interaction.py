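"""Score-by-sex moderation tests.

Two designs are offered: a naive model adding only the score x sex
product to the main-effects regression, and a robust model that also
enters every covariate x score and covariate x sex product as nuisance
terms so that confounded moderation does not masquerade as a sex
interaction.  Sex is coded 0 = reference (female), 1 = male; the
interaction beta is the male-minus-reference difference in the per-SD
score effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from prsphewas.phewas import PhenotypeTable, PhewasError, _ols, adjusted_r2, bh_adjust
from prsphewas.scoring import ScoreVector

__all__ = ["InteractionResult", "fit_interaction", "run_interaction_scan", "flag_significant_interactions"]


@dataclass
class InteractionResult:
    prs_name: str
    phenotype: str
    wave: str
    n: int
    model: str  # "naive" | "robust"
    beta_main: float
    se_main: float
    p_main: float
    beta_int: float
    se_int: float
    p_int: float
    q_main: float = np.nan
    q_int: float = np.nan
    delta_adj_r2_int: float = np.nan  # percent scale

    def to_dict(self) -> dict:
        return {
            "prs_name": self.prs_name,
            "phenotype": self.phenotype,
            "wave": self.wave,
            "n": self.n,
            "model": self.model,
            "beta_main": self.beta_main,
            "se_main": self.se_main,
            "p_main": self.p_main,
            "q_main": self.q_main,
            "beta_int": self.beta_int,
            "se_int": self.se_int,
            "p_int": self.p_int,
            "q_int": self.q_int,
            "delta_adj_r2_int_pct": self.delta_adj_r2_int,
        }


def _interaction_design(
    s: np.ndarray, sex: np.ndarray, cov: np.ndarray, model: str
) -> tuple[np.ndarray, list[str]]:
    n = s.size
    cols = [np.ones(n), s, sex]
    names = ["intercept", "score", "sex"]
    for j in range(cov.shape[1]):
        cols.append(cov[:, j])
        names.append(f"cov{j}")
    if model == "robust":
        for j in range(cov.shape[1]):
            cols.append(cov[:, j] * s)
            names.append(f"cov{j}:score")
            cols.append(cov[:, j] * sex)
            names.append(f"cov{j}:sex")
    cols.append(s * sex)
    names.append("score:sex")
    return np.column_stack(cols), names


def fit_interaction(
    y: np.ndarray,
    s: np.ndarray,
    sex: np.ndarray,
    cov: np.ndarray | None = None,
    model: str = "robust",
    prs_name: str = "prs",
    phenotype: str = "phenotype",
    wave: str = "w1",
) -> InteractionResult:
    """Fit y ~ score + sex + cov (+ products) + score x sex; test both terms.

    ``model="robust"`` adds cov_j x score and cov_j x sex for every
    covariate column.  ``delta_adj_r2_int`` is the adjusted-R2 gain of the
    score x sex column over the same design without it, percent scale.
    """
    if model not in ("naive", "robust"):
        raise PhewasError(f"unknown interaction model {model!r}")
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if cov is None:
        cov = np.empty((y.size, 0))
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    ok = (
        np.isfinite(y)
        & np.isfinite(s)
        & np.isfinite(sex)
        & np.all(np.isfinite(cov), axis=1)
    )
    y, s, sex, cov = y[ok], s[ok], sex[ok], cov[ok]
    levels = np.unique(sex)
    if not np.all(np.isin(levels, (0.0, 1.0))):
        raise PhewasError("sex must be coded 0/1")
    if levels.size < 2:
        raise PhewasError("single-sex sample: interaction is not identifiable")
    X, names = _interaction_design(s, sex, cov, model)
    try:
        beta, se, rss, df_resid = _ols(y, X)
    except PhewasError as exc:
        raise PhewasError(f"{model} interaction design is singular: {exc}") from exc
    n = y.size
    i_s, i_int = names.index("score"), names.index("score:sex")

    def term(i: int) -> tuple[float, float, float]:
        t = beta[i] / se[i]
        return float(beta[i]), float(se[i]), float(2.0 * stats.t.sf(abs(t), df_resid))

    b_s, se_s, p_s = term(i_s)
    b_i, se_i, p_i = term(i_int)
    tss = float(((y - y.mean()) ** 2).sum())
    X_red = np.delete(X, i_int, axis=1)
    _, _, rss_red, _ = _ols(y, X_red)
    k_full, k_red = X.shape[1] - 1, X_red.shape[1] - 1
    delta = adjusted_r2(1 - rss / tss, n, k_full) - adjusted_r2(1 - rss_red / tss, n, k_red)
    return InteractionResult(
        prs_name=prs_name,
        phenotype=phenotype,
        wave=wave,
        n=n,
        model=model,
        beta_main=b_s,
        se_main=se_s,
        p_main=p_s,
        beta_int=b_i,
        se_int=se_i,
        p_int=p_i,
        delta_adj_r2_int=100.0 * delta,
    )


def run_interaction_scan(
    scores: Sequence[ScoreVector],
    pt: PhenotypeTable,
    model: str = "robust",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Interaction fit for every score x phenotype x wave; BH per score family.

    Main-effect and interaction p-values are adjusted separately, each
    within the per-score family, mirroring the association scan.
    """
    pairs = pt.phenotype_waves()
    rows: list[InteractionResult] = []
    for sv in scores:
        if sv.standardized is None:
            raise PhewasError(f"score {sv.prs_name} is not standardized")
        sdf = pd.DataFrame({"sample_id": sv.samples, "_score": sv.standardized})
        base = pt.samples.merge(sdf, on="sample_id", how="inner")
        fam: list[InteractionResult] = []
        for row in pairs.itertuples(index=False):
            meas = pt.measurements[
                (pt.measurements["phenotype"] == row.phenotype)
                & (pt.measurements["wave"] == row.wave)
            ]
            df = base.merge(meas[["sample_id", "age", "value"]], on="sample_id", how="inner")
            cov_cols = list(pt.pc_columns)
            if not pt.is_age_of_initiation(row.phenotype):
                cov_cols.insert(0, "age")
            df = df.dropna(subset=["value", "_score", "sex", *cov_cols])
            try:
                fam.append(
                    fit_interaction(
                        df["value"].to_numpy(),
                        df["_score"].to_numpy(),
                        df["sex"].to_numpy(),
                        df[cov_cols].to_numpy(),
                        model=model,
                        prs_name=sv.prs_name,
                        phenotype=str(row.phenotype),
                        wave=str(row.wave),
                    )
                )
            except PhewasError:
                continue
        if fam:
            q_main = bh_adjust([r.p_main for r in fam])
            q_int = bh_adjust([r.p_int for r in fam])
            for r, qm, qi in zip(fam, q_main, q_int):
                r.q_main, r.q_int = float(qm), float(qi)
            rows.extend(fam)
    return pd.DataFrame([r.to_dict() for r in rows])


def flag_significant_interactions(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep rows where both the main effect and the interaction pass q < alpha."""
    if results.empty:
        return results.copy()
    mask = (results["q_main"] < alpha) & (results["q_int"] < alpha)
    return results[mask].reset_index(drop=True)
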