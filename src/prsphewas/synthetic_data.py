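"""Seeded synthetic genotypes, weights, annotation and phenotypes.

Everything needed to exercise the pipeline end to end without external
data: genotypes in Hardy-Weinberg proportions at configurable MAFs,
sparse weight vectors (optionally concentrated in a planted pathway's
genes), longitudinal phenotypes with a configured variance-explained
trajectory, sex and sex-interaction effects, covariate structure, and a
toy genome emitted as GFF3/BED + GMT.  A single seed drives every stage
through derived substreams, so outputs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from prsphewas.genio import (
    GeneModel,
    GenotypeMatrix,
    VariantRecord,
    WeightSet,
    write_genotypes_tsv,
    write_gmt,
    write_weights,
)
from prsphewas.pathways import map_snps_to_genes
from prsphewas.scoring import compute_prs, standardize

__all__ = [
    "SimConfig",
    "gen_genotypes",
    "gen_weights",
    "gen_phenotypes",
    "gen_annotation",
    "write_fixture",
    "write_gff3",
    "write_bed",
]

# substream tags so stages draw from independent, seed-derived generators
_STREAM_GENO, _STREAM_WEIGHTS, _STREAM_PHENO, _STREAM_ANNOT = 11, 23, 37, 53


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    n_samples: int = 1000
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    weight_sparsity: float = 0.2
    target_r2: float = 0.03
    sex_effect: float = 0.0
    sex_interaction_effect: float = 0.0
    pc_effect: float = 0.02
    ages: tuple[float, ...] = (16.0,)
    r2_trajectory: str = "constant"  # constant | linear_decline | quadratic
    trajectory_params: dict = field(default_factory=dict)
    phenotype_name: str = "phen1"
    phenotype_category: str = "substance_use"
    n_null_phenotypes: int = 0
    null_categories: tuple[str, ...] = ("substance_use", "gambling", "eating", "internet_use")
    n_genes: int = 50
    n_pathways: int = 10
    pathway_size: int = 8
    planted_pathway: str | None = None
    concentration: float = 5.0
    window_bp: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("missing_rate", self.missing_rate),
            ("weight_sparsity", self.weight_sparsity),
            ("target_r2", self.target_r2),
        ):
            if not (0.0 <= v <= 1.0):
                raise SimError(f"{name}={v} outside [0,1]")
        if self.target_r2 >= 1.0:
            raise SimError("target_r2 must be < 1")
        if list(self.ages) != sorted(set(self.ages)):
            raise SimError("ages must be strictly increasing")

    def r2_at(self, age: float) -> float:
        """Variance-explained trajectory evaluated at one wave age."""
        ages = self.ages
        if self.r2_trajectory == "constant":
            return self.target_r2
        lo, hi = ages[0], ages[-1]
        span = max(hi - lo, 1e-12)
        if self.r2_trajectory == "linear_decline":
            r2_start = self.trajectory_params.get("r2_start", self.target_r2)
            r2_end = self.trajectory_params.get("r2_end", self.target_r2 / 4)
            return r2_start + (r2_end - r2_start) * (age - lo) / span
        if self.r2_trajectory == "quadratic":
            # parabola through (lo, r2_start), (mid, r2_mid), (hi, r2_end)
            p = self.trajectory_params
            r2_s = p.get("r2_start", self.target_r2 / 2)
            r2_m = p.get("r2_mid", self.target_r2)
            r2_e = p.get("r2_end", self.target_r2 / 2)
            t = 2.0 * (age - lo) / span - 1.0  # -1..1
            return r2_m + (r2_e - r2_s) / 2.0 * t + (r2_s + r2_e - 2 * r2_m) / 2.0 * t * t
        raise SimError(f"unknown r2_trajectory {self.r2_trajectory!r}")


def _rng(cfg: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def gen_annotation(cfg: SimConfig) -> tuple[list[GeneModel], dict[str, set[str]]]:
    """Toy genome: genes on 1-2 chromosomes with a few deliberate overlaps,
    plus random pathways and (optionally) the planted pathway."""
    rng = _rng(cfg, _STREAM_ANNOT)
    genes: list[GeneModel] = []
    chroms = ["1", "2"] if cfg.n_genes > 20 else ["1"]
    per_chrom = int(np.ceil(cfg.n_genes / len(chroms)))
    i = 0
    for chrom in chroms:
        cursor = 50_000
        for _ in range(per_chrom):
            if i >= cfg.n_genes:
                break
            length = int(rng.integers(10_000, 50_000))
            start = cursor
            genes.append(GeneModel(f"gene{i:04d}", chrom, start, start + length))
            # every 7th gene overlaps its successor's window deliberately
            gap = int(rng.integers(5_000, 40_000)) if i % 7 == 6 else int(rng.integers(220_000, 320_000))
            cursor = start + length + gap
            i += 1
    gene_ids = [g.gene_id for g in genes]
    pathways: dict[str, set[str]] = {}
    for p in range(cfg.n_pathways):
        size = min(cfg.pathway_size, len(gene_ids))
        pathways[f"pw{p:03d}"] = set(rng.choice(gene_ids, size=size, replace=False))
    if cfg.planted_pathway is not None:
        size = min(cfg.pathway_size, len(gene_ids))
        pathways[cfg.planted_pathway] = set(rng.choice(gene_ids, size=size, replace=False))
    return genes, pathways


def gen_genotypes(cfg: SimConfig, genes: list[GeneModel] | None = None) -> GenotypeMatrix:
    """HWE dosages at per-variant MAFs with MCAR missingness.

    Variant positions are spread over the toy genome when ``genes`` is
    given (so gene mapping is exercised), else placed on chromosome 1 at
    fixed spacing.
    """
    rng = _rng(cfg, _STREAM_GENO)
    n, v = cfg.n_samples, cfg.n_variants
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=v)
    dosages = rng.binomial(2, mafs, size=(n, v)).astype(float)
    if cfg.missing_rate > 0:
        miss = rng.random(size=(n, v)) < cfg.missing_rate
        dosages[miss] = np.nan
    if genes:
        chrom_max: dict[str, int] = {}
        for gm in genes:
            chrom_max[gm.chrom] = max(chrom_max.get(gm.chrom, 0), gm.end + 200_000)
        chrom_list = sorted(chrom_max)
        chrom_idx = rng.integers(0, len(chrom_list), size=v)
        positions = np.array(
            [int(rng.integers(1, chrom_max[chrom_list[c]])) for c in chrom_idx]
        )
        chrom_names = [chrom_list[c] for c in chrom_idx]
    else:
        chrom_names = ["1"] * v
        positions = 10_000 * (np.arange(v) + 1)
    allele_pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "T"), ("G", "A")]
    pair_idx = rng.integers(0, len(allele_pairs), size=v)
    variants = [
        VariantRecord(
            variant_id=f"var{j:05d}",
            chrom=chrom_names[j],
            pos=int(positions[j]),
            allele_a1=allele_pairs[pair_idx[j]][0],
            allele_a2=allele_pairs[pair_idx[j]][1],
            info_r2=float(rng.uniform(0.6, 1.0)),
        )
        for j in range(v)
    ]
    samples = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def gen_weights(
    cfg: SimConfig,
    g: GenotypeMatrix,
    genes: list[GeneModel] | None = None,
    pathways: dict[str, set[str]] | None = None,
    prs_name: str = "prs_sim",
) -> WeightSet:
    """Sparse standard-normal weights; zero otherwise.

    With a planted pathway, variants mapping into its genes (+/- the
    configured window) are non-zero with probability ``concentration``
    times the background sparsity (capped at 1).
    """
    if cfg.weight_sparsity <= 0:
        raise SimError("weight_sparsity must be > 0: an all-zero score is degenerate")
    rng = _rng(cfg, _STREAM_WEIGHTS)
    v = g.n_variants
    prob = np.full(v, cfg.weight_sparsity)
    if cfg.planted_pathway is not None:
        if genes is None or pathways is None:
            raise SimError("planted_pathway requires annotation (genes + pathways)")
        planted_genes = pathways[cfg.planted_pathway]
        entries = pd.DataFrame(
            {
                "variant_id": g.variant_ids(),
                "chrom": [x.chrom for x in g.variants],
                "pos": [x.pos for x in g.variants],
            }
        )
        snp_map = map_snps_to_genes(entries.assign(weight=1.0), genes, cfg.window_bp)
        in_planted = np.array(
            [bool(snp_map.entries.get(vid, set()) & planted_genes) for vid in g.variant_ids()]
        )
        prob = np.where(in_planted, np.minimum(1.0, cfg.concentration * cfg.weight_sparsity), prob)
    nonzero = rng.random(v) < prob
    weights = np.where(nonzero, rng.normal(size=v), 0.0)
    entries = pd.DataFrame(
        {
            "variant_id": g.variant_ids(),
            "chrom": [x.chrom for x in g.variants],
            "pos": [x.pos for x in g.variants],
            "effect_allele": [x.allele_a1 for x in g.variants],
            "other_allele": [x.allele_a2 for x in g.variants],
            "weight": weights,
        }
    )
    return WeightSet(prs_name, entries)


def solve_beta(r2: float, var_other: float) -> float:
    """Per-SD effect giving fraction ``r2`` of total variance for a
    unit-variance score on top of ``var_other`` residual+covariate variance."""
    if not (0.0 <= r2 < 1.0):
        raise SimError(f"variance-explained target {r2} outside [0,1)")
    return float(np.sqrt(r2 * var_other / (1.0 - r2)))


def gen_phenotypes(
    g: GenotypeMatrix,
    w: WeightSet,
    cfg: SimConfig,
    causal_weights: WeightSet | None = None,
):
    """Longitudinal phenotypes driven by the (standardized) true score.

    For each wave at age ``a``:
    ``y = beta(a)*score + gamma*sex + delta*sex*score + sum(c*pc) + eps``
    with ``beta(a)`` solved so the population variance explained equals
    the configured trajectory at ``a``.  Returns a
    :class:`~prsphewas.phewas.PhenotypeTable` plus the ground-truth dict.
    """
    from prsphewas.phewas import PhenotypeTable

    rng = _rng(cfg, _STREAM_PHENO)
    true_w = causal_weights if causal_weights is not None else w
    score = standardize(compute_prs(g, true_w)).standardized
    n = g.n_samples
    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.normal(size=(n, 10))
    gamma, delta, c = cfg.sex_effect, cfg.sex_interaction_effect, cfg.pc_effect
    var_other = gamma**2 * 0.25 + delta**2 * 0.5 + 10 * c**2 + 1.0
    samples = pd.DataFrame({"sample_id": g.samples, "sex": sex.astype(int)})
    for j in range(10):
        samples[f"pc{j + 1}"] = pcs[:, j]
    meas_rows = []
    truth_betas = {}
    for wi, age in enumerate(cfg.ages):
        wave = f"w{wi + 1}"
        r2 = cfg.r2_at(age)
        beta = solve_beta(r2, var_other)
        truth_betas[wave] = {"age": age, "r2": r2, "beta": beta}
        eps = rng.normal(size=n)
        y = beta * score + gamma * sex + delta * sex * score + pcs @ np.full(10, c) + eps
        age_i = age + rng.uniform(-0.5, 0.5, size=n)
        meas_rows.append(
            pd.DataFrame(
                {
                    "sample_id": g.samples,
                    "phenotype": cfg.phenotype_name,
                    "wave": wave,
                    "age": age_i,
                    "value": y,
                }
            )
        )
    meta_rows = [
        {
            "phenotype": cfg.phenotype_name,
            "category": cfg.phenotype_category,
            "is_age_of_initiation": False,
        }
    ]
    for k in range(cfg.n_null_phenotypes):
        name = f"null{k:03d}"
        cat = cfg.null_categories[k % len(cfg.null_categories)]
        y = rng.normal(size=n)
        age_i = cfg.ages[0] + rng.uniform(-0.5, 0.5, size=n)
        meas_rows.append(
            pd.DataFrame(
                {"sample_id": g.samples, "phenotype": name, "wave": "w1", "age": age_i, "value": y}
            )
        )
        meta_rows.append({"phenotype": name, "category": cat, "is_age_of_initiation": False})
    pt = PhenotypeTable(
        samples=samples,
        measurements=pd.concat(meas_rows, ignore_index=True),
        meta=pd.DataFrame(meta_rows),
    )
    truth = {
        "waves": truth_betas,
        "sex_effect": gamma,
        "sex_interaction_effect": delta,
        "pc_effect": c,
        "var_other": var_other,
    }
    return pt, truth


# ---------------------------------------------------------------------------
# fixture writers
# ---------------------------------------------------------------------------

def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in genes:
            fh.write(
                f"{gm.chrom}\tsim\tgene\t{gm.start}\t{gm.end}\t.\t+\t.\tID={gm.gene_id}\n"
            )


def write_bed(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gm in genes:
            fh.write(f"{gm.chrom}\t{gm.start - 1}\t{gm.end}\t{gm.gene_id}\n")


def write_fixture(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate a complete on-disk fixture directory; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, pathways = gen_annotation(cfg)
    g = gen_genotypes(cfg, genes)
    w = gen_weights(cfg, g, genes, pathways)
    pt, truth = gen_phenotypes(g, w, cfg)
    write_genotypes_tsv(g, outdir / "genotypes.tsv", outdir / "variants.tsv")
    write_weights(w, outdir / "weights.tsv")
    pt.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    pt.measurements.to_csv(outdir / "measurements.tsv", sep="\t", index=False)
    pt.meta.to_csv(outdir / "phenotype_meta.tsv", sep="\t", index=False)
    write_gff3(genes, outdir / "genes.gff3")
    write_bed(genes, outdir / "genes.bed")
    write_gmt(pathways, outdir / "pathways.gmt")
    manifest = {"config": asdict(cfg), "truth": truth}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
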