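"""Polygenic score computation and standardization.

A raw score is the weighted sum of effect-allele dosages over the
variants shared by a harmonized :class:`~prsphewas.genio.WeightSet` and a
:class:`~prsphewas.genio.GenotypeMatrix`.  Standardization rescales raw
scores to mean zero and unit variance over the full scored sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from prsphewas.genio import GenioError, GenotypeMatrix, WeightSet

__all__ = ["ScoreVector", "compute_prs", "standardize", "restrict_weights", "write_scores"]


class ScoringError(ValueError):
    pass


@dataclass
class ScoreVector:
    prs_name: str
    samples: list[str]
    raw: np.ndarray
    standardized: np.ndarray | None = None
    n_snps_used: int = 0

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.samples) != self.raw.size:
            raise ScoringError("sample/raw length mismatch")
        if not np.all(np.isfinite(self.raw)):
            raise ScoringError("non-finite raw scores")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.samples,
                "prs_name": self.prs_name,
                "raw": self.raw,
                "standardized": self.standardized if self.standardized is not None else np.nan,
            }
        )


def compute_prs(
    g: GenotypeMatrix, w: WeightSet, missing_policy: str = "mean_impute"
) -> ScoreVector:
    """Raw score per sample: sum over shared variants of weight x dosage.

    ``mean_impute`` replaces a missing dosage by that variant's mean over
    non-missing samples; ``omit`` drops the term for that sample.
    """
    if missing_policy not in ("mean_impute", "omit"):
        raise ScoringError(f"unknown missing_policy {missing_policy!r}")
    idx = {vid: j for j, vid in enumerate(g.variant_ids())}
    cols: list[int] = []
    weights: list[float] = []
    for row in w.entries.itertuples(index=False):
        j = idx.get(row.variant_id)
        if j is not None:
            cols.append(j)
            weights.append(float(row.weight))
    if not cols:
        raise ScoringError(
            f"weight set {w.prs_name}: no overlapping variants with genotype data"
        )
    d = g.dosages[:, cols].copy()
    miss = ~np.isfinite(d)
    if miss.any():
        if missing_policy == "mean_impute":
            col_all_missing = miss.all(axis=0)
            if col_all_missing.any():
                bad = g.variants[cols[int(np.argmax(col_all_missing))]].variant_id
                raise ScoringError(f"variant {bad}: all dosages missing, cannot mean-impute")
            col_means = np.nanmean(d, axis=0)
            d[miss] = np.broadcast_to(col_means, d.shape)[miss]
        else:
            d[miss] = 0.0
    raw = d @ np.asarray(weights)
    return ScoreVector(
        prs_name=w.prs_name, samples=list(g.samples), raw=raw, n_snps_used=len(cols)
    )


def standardize(sv: ScoreVector) -> ScoreVector:
    """Return a copy with standardized = (raw - mean) / sd (n-1 denominator)."""
    if sv.raw.size < 2:
        raise ScoringError("need >= 2 samples to standardize")
    mean = sv.raw.mean()
    sd = sv.raw.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise ScoringError(f"score {sv.prs_name} is degenerate: zero variance")
    return replace(sv, standardized=(sv.raw - mean) / sd)


def restrict_weights(w: WeightSet, variant_subset: Iterable[str]) -> WeightSet:
    """Weight set restricted to ``variant_subset`` (used for pathway partitions)."""
    subset = set(variant_subset)
    sub = w.entries[w.entries["variant_id"].isin(subset)].reset_index(drop=True)
    if sub.empty:
        raise ScoringError(
            f"weight set {w.prs_name}: restriction to {len(subset)} ids left no entries"
        )
    return WeightSet(w.prs_name, sub)


def write_scores(scores: Sequence[ScoreVector], path: str | Path) -> None:
    pd.concat([sv.to_frame() for sv in scores], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
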