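"""Pathway-partitioned scores.

Non-zero-weight variants of an eligible score are mapped to every gene
whose window-extended interval covers them (default +/- 100 kb); the
mapped gene set is tested for pathway over-representation with a
one-sided hypergeometric test; and for each enriched pathway a
restricted score is built from the variants mapping (via genes) into it
and re-scanned against the full phenome.  A variant inside several
genes' windows can feed several pathway scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from prsphewas.genio import GeneModel, GenioError, GenotypeMatrix, WeightSet
from prsphewas.phewas import PhenotypeTable, bh_adjust, run_phewas
from prsphewas.scoring import ScoreVector, ScoringError, compute_prs, restrict_weights, standardize

__all__ = [
    "SnpGeneMap",
    "EnrichmentResult",
    "select_partition_eligible",
    "map_snps_to_genes",
    "enrich_pathways",
    "build_partitioned_scores",
    "run_partitioned_phewas",
]


class PathwayError(ValueError):
    pass


@dataclass
class SnpGeneMap:
    """variant_id -> set of gene ids within the window; unmapped recorded."""

    entries: dict[str, set[str]]
    window_bp: int
    unmapped: list[str] = field(default_factory=list)

    def mapped_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.entries.values():
            out |= genes
        return out

    def genes_to_snps(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for vid, genes in self.entries.items():
            for gid in genes:
                inv.setdefault(gid, set()).add(vid)
        return inv

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variant_id": vid, "gene_id": gid}
            for vid, genes in self.entries.items()
            for gid in sorted(genes)
        ]
        return pd.DataFrame(rows, columns=["variant_id", "gene_id"])


@dataclass
class EnrichmentResult:
    pathway: str
    k: int  # mapped genes in pathway
    m: int  # pathway size within background
    K: int  # mapped genes in background
    N: int  # background size
    p: float
    q: float = np.nan
    enriched: bool = False

    def to_dict(self) -> dict:
        return {
            "pathway": self.pathway,
            "k": self.k,
            "m": self.m,
            "K": self.K,
            "N": self.N,
            "p": self.p,
            "q": self.q,
            "enriched": self.enriched,
        }


def select_partition_eligible(
    results: pd.DataFrame,
    pt: PhenotypeTable,
    min_delta_adj_r2_pct: float = 1.0,
    alpha: float = 0.05,
) -> list[str]:
    """Scores worth partitioning: max delta adj-R2 above the floor AND at
    least one q < alpha association in every phenotype category."""
    categories = set(pt.meta["category"].dropna().unique())
    if not categories:
        raise PathwayError("no phenotype categories defined")
    cat_of = dict(zip(pt.meta["phenotype"], pt.meta["category"]))
    res = results.copy()
    res["category"] = res["phenotype"].map(cat_of)
    eligible = []
    for prs, sub in res.groupby("prs_name", sort=True):
        if sub["delta_adj_r2_pct"].max() <= min_delta_adj_r2_pct:
            continue
        sig_cats = set(sub.loc[sub["q"] < alpha, "category"].dropna().unique())
        if sig_cats >= categories:
            eligible.append(str(prs))
    return eligible


def map_snps_to_genes(
    w_nonzero: WeightSet | pd.DataFrame,
    genes: Sequence[GeneModel],
    window_bp: int = 100_000,
) -> SnpGeneMap:
    """Map variants to all genes whose +/-window interval covers them.

    The window rule is inclusive at exactly ``window_bp`` base pairs from
    a gene boundary.
    """
    if window_bp < 0:
        raise PathwayError(f"window_bp must be >= 0, got {window_bp}")
    entries_df = w_nonzero.entries if isinstance(w_nonzero, WeightSet) else w_nonzero
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in genes:
        by_chrom.setdefault(gm.chrom, []).append(gm)
    mapping: dict[str, set[str]] = {}
    unmapped: list[str] = []
    for row in entries_df.itertuples(index=False):
        vid, chrom, pos = str(row.variant_id), str(row.chrom), int(row.pos)
        hits = {
            gm.gene_id
            for gm in by_chrom.get(chrom, ())
            if gm.start - window_bp <= pos <= gm.end + window_bp
        }
        if hits:
            mapping[vid] = hits
        else:
            unmapped.append(vid)
    return SnpGeneMap(entries=mapping, window_bp=window_bp, unmapped=unmapped)


def hypergeom_enrich_p(k: int, N: int, m: int, K: int) -> float:
    """Upper-tail P(X >= k) for drawing K genes from N with m marked."""
    if not (0 <= k <= min(m, K)):
        raise PathwayError(f"impossible counts k={k}, m={m}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, m, K))


def enrich_pathways(
    snp_map: SnpGeneMap,
    pathways: Mapping[str, set[str]],
    background: set[str] | None = None,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of mapped genes per pathway.

    Counts are unique genes.  ``background`` defaults to the union of the
    annotation's pathway genes and the mapped genes; pathways and the
    mapped set are intersected with it.  BH across pathways; enriched iff
    q < ``alpha``.
    """
    mapped = snp_map.mapped_genes()
    if not mapped:
        raise PathwayError("no mapped genes: cannot test enrichment")
    if background is None:
        background = set().union(*pathways.values()) | mapped if pathways else set(mapped)
    mapped_bg = mapped & background
    results = []
    for name in sorted(pathways):
        pw_genes = pathways[name] & background
        k = len(pw_genes & mapped_bg)
        res = EnrichmentResult(
            pathway=name,
            k=k,
            m=len(pw_genes),
            K=len(mapped_bg),
            N=len(background),
            p=hypergeom_enrich_p(k, len(background), len(pw_genes), len(mapped_bg)),
        )
        results.append(res)
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        r.enriched = bool(q < alpha)
    return results


def build_partitioned_scores(
    w: WeightSet,
    snp_map: SnpGeneMap,
    enriched: Sequence[str],
    pathways: Mapping[str, set[str]],
    g: GenotypeMatrix,
    missing_policy: str = "mean_impute",
) -> list[ScoreVector]:
    """One standardized score per enriched pathway, from the variants whose
    gene set intersects it.  Pathways with zero assigned variants are
    skipped with a warning recorded on the returned list's frames."""
    if not enriched:
        raise PathwayError("no enriched pathways to partition by")
    import warnings

    nz = w.nonzero()
    scores: list[ScoreVector] = []
    for name in enriched:
        genes = pathways.get(name)
        if genes is None:
            raise PathwayError(f"pathway {name!r} not in database")
        vids = {vid for vid, gset in snp_map.entries.items() if gset & genes}
        vids &= set(nz.variant_ids())
        if not vids:
            warnings.warn(f"pathway {name!r}: zero assigned variants, skipped")
            continue
        sub = restrict_weights(nz, vids)
        sub.prs_name = f"{w.prs_name}|{name}"
        sv = standardize(compute_prs(g, sub, missing_policy=missing_policy))
        scores.append(sv)
    return scores


def run_partitioned_phewas(
    partitioned: Sequence[ScoreVector], pt: PhenotypeTable, alpha: float = 0.05
) -> pd.DataFrame:
    """Full phenome scan of every partitioned score (BH per partition)."""
    return run_phewas(list(partitioned), pt, alpha=alpha)
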