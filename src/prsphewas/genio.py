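"""Format I/O, variant quality control and weight-file harmonization.

Readers return plain dataclasses backed by numpy arrays; missing dosages
are carried as NaN throughout.  The dosage TSV dialect is documented in
the README: a header row of variant ids, one row per sample, ``NA`` for
missing, with variant metadata in an optional sidecar table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "WeightSet",
    "QCThresholds",
    "GeneModel",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_weights",
    "write_weights",
    "read_gene_models",
    "read_gmt",
    "write_gmt",
    "hwe_exact_test",
    "qc_filter",
    "harmonize_weights",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NUCS = frozenset("ACGT")


class GenioError(ValueError):
    """Raised on malformed input files or invalid genetic-data operations."""


@dataclass(frozen=True)
class VariantRecord:
    """A single bi-allelic variant.

    ``allele_a1`` is the counted (effect) allele of the dosage encoding;
    ``allele_a2`` the other allele.  ``chrom``/``pos`` may be ``None`` for
    dosage-only inputs that carry no coordinates.
    """

    variant_id: str
    chrom: str | None = None
    pos: int | None = None
    allele_a1: str = "A"
    allele_a2: str = "G"
    info_r2: float | None = None

    def __post_init__(self) -> None:
        if self.pos is not None and self.pos < 1:
            raise GenioError(f"variant {self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.allele_a1 == self.allele_a2:
            raise GenioError(f"variant {self.variant_id}: alleles must differ")
        if self.info_r2 is not None and not (0.0 <= self.info_r2 <= 1.0):
            raise GenioError(f"variant {self.variant_id}: info_r2 outside [0,1]")

    @property
    def is_snp(self) -> bool:
        """True when both alleles are single nucleotides (strand logic applies)."""
        return self.allele_a1 in _NUCS and self.allele_a2 in _NUCS

    @property
    def is_ambiguous(self) -> bool:
        """A/T or C/G pair: indistinguishable from its strand complement."""
        return self.is_snp and _COMPLEMENT[self.allele_a1] == self.allele_a2


@dataclass
class GenotypeMatrix:
    """Sample-by-variant dosage matrix; NaN marks missing entries."""

    samples: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray  # shape (n_samples, n_variants), float, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise GenioError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise GenioError("duplicate sample ids")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise GenioError("duplicate variant ids")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            raise GenioError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in keep],
            dosages=self.dosages[:, keep].copy(),
        )


@dataclass
class WeightSet:
    """Per-variant effect weights defining one polygenic score."""

    prs_name: str
    entries: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele, weight

    COLUMNS = ("variant_id", "chrom", "pos", "effect_allele", "other_allele", "weight")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.entries.columns]
        if missing:
            raise GenioError(f"weight set {self.prs_name}: missing columns {missing}")
        self.entries = self.entries.reset_index(drop=True)
        if self.entries["variant_id"].duplicated().any():
            dups = self.entries.loc[self.entries["variant_id"].duplicated(), "variant_id"]
            raise GenioError(f"weight set {self.prs_name}: duplicate variant ids {list(dups[:3])}")
        w = self.entries["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise GenioError(f"weight set {self.prs_name}: non-finite weights")

    def __len__(self) -> int:
        return len(self.entries)

    def nonzero(self) -> "WeightSet":
        """Entries with weight exactly != 0 (the pathway-mapping universe)."""
        sub = self.entries[self.entries["weight"] != 0.0].reset_index(drop=True)
        return WeightSet(self.prs_name, sub)

    def variant_ids(self) -> list[str]:
        return self.entries["variant_id"].tolist()


@dataclass(frozen=True)
class QCThresholds:
    """Variant retention thresholds; comparisons are strict as documented."""

    min_maf: float = 0.01
    max_missing: float = 0.05
    min_hwe_p: float = 5e-7
    min_info_r2: float = 0.3

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_missing", "min_hwe_p", "min_info_r2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise GenioError(f"QC threshold {name}={v} outside [0,1]")


@dataclass(frozen=True)
class GeneModel:
    """Gene interval, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise GenioError(f"gene {self.gene_id}: end {self.end} < start {self.start}")


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    variants_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a dosage matrix from VCF or the documented TSV dialect.

    VCF dosages come from the per-sample ``DS`` field when present, else
    from hard genotype calls (0/1/2); multi-allelic records are rejected.
    For the TSV dialect, ``variants_path`` may name a sidecar table
    (variant_id, chrom, pos, allele_a1, allele_a2[, info_r2]) supplying
    coordinates and alleles.
    """
    path = Path(path)
    if not path.exists():
        raise GenioError(f"genotype file not found: {path}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_dosage_tsv(path, variants_path)
    raise GenioError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise GenioError(
                f"{path}: record {i + 1} ({rec.CHROM}:{rec.POS}) is not bi-allelic "
                f"(ALT={rec.ALT}); retain unique bi-allelic SNPs upstream"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        if vid in seen:
            raise GenioError(f"{path}: duplicate variant id {vid!r} at record {i + 1}")
        seen.add(vid)
        info_r2 = rec.INFO.get("R2")
        variants.append(
            VariantRecord(
                variant_id=vid,
                chrom=rec.CHROM,
                pos=rec.POS,
                allele_a1=rec.ALT[0],
                allele_a2=rec.REF,
                info_r2=float(info_r2) if info_r2 is not None else None,
            )
        )
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
            gt = np.asarray(rec.gt_types)
            col = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        col = np.where(np.isfinite(col), col, np.nan)
        columns.append(col)
    if not variants:
        raise GenioError(f"{path}: no variant records")
    dosages = np.column_stack(columns)
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def _read_dosage_tsv(path: Path, variants_path: str | Path | None) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header[1:])) != len(header[1:]):
        raise GenioError(f"{path}: duplicate variant ids in header")
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"], keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise GenioError(f"{path}: failed to parse dosage TSV: {exc}") from exc
    if df.columns[0] != "sample_id":
        raise GenioError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    variant_ids = list(df.columns[1:])
    if len(set(variant_ids)) != len(variant_ids):
        raise GenioError(f"{path}: duplicate variant ids in header")
    meta: dict[str, VariantRecord] = {}
    if variants_path is not None:
        vdf = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
        for row in vdf.itertuples(index=False):
            meta[str(row.variant_id)] = VariantRecord(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                allele_a1=str(row.allele_a1),
                allele_a2=str(row.allele_a2),
                info_r2=float(row.info_r2) if "info_r2" in vdf.columns and pd.notna(row.info_r2) else None,
            )
    variants = [meta.get(vid, VariantRecord(variant_id=vid)) for vid in variant_ids]
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(samples=df["sample_id"].astype(str).tolist(), variants=variants, dosages=dosages)


def write_genotypes_tsv(
    g: GenotypeMatrix, path: str | Path, variants_path: str | Path | None = None
) -> None:
    """Write the TSV dialect (and the variant sidecar when requested).

    Dosages are written with :func:`repr`-grade precision so a read/write
    cycle round-trips them bit-exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(g.variant_ids()) + "\n")
        for s, row in zip(g.samples, g.dosages):
            cells = ["NA" if not np.isfinite(d) else repr(float(d)) for d in row]
            fh.write(s + "\t" + "\t".join(cells) + "\n")
    if variants_path is not None:
        rows = []
        for v in g.variants:
            rows.append(
                {
                    "variant_id": v.variant_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "allele_a1": v.allele_a1,
                    "allele_a2": v.allele_a2,
                    "info_r2": v.info_r2,
                }
            )
        pd.DataFrame(rows).to_csv(variants_path, sep="\t", index=False)


def read_weights(path: str | Path, prs_name: str | None = None) -> WeightSet:
    """Read a weight TSV (variant_id, chrom, pos, effect_allele, other_allele, weight)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "variant_id": str})
    name = prs_name if prs_name is not None else Path(path).stem
    return WeightSet(name, df[list(WeightSet.COLUMNS)])


def write_weights(w: WeightSet, path: str | Path) -> None:
    w.entries.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models and pathway sets
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene intervals from GFF3 (1-based inclusive) or BED (converted).

    BED's 0-based half-open [start, end) becomes 1-based inclusive
    [start+1, end].
    """
    path = Path(path)
    if format == "gff3":
        return _read_gff3_genes(path)
    if format == "bed":
        return _read_bed_genes(path)
    raise GenioError(f"unknown gene-model format: {format!r}")


def _read_gff3_genes(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gene_id=gid, chrom=feat.seqid, start=feat.start, end=feat.end))
    if not genes:
        raise GenioError(f"{path}: no gene features found")
    return genes


def _read_bed_genes(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise GenioError(f"{path}:{lineno}: BED line needs >= 4 fields")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if end < start:
                raise GenioError(f"{path}:{lineno}: end < start")
            genes.append(GeneModel(gene_id=name, chrom=chrom, start=start + 1, end=end))
    if not genes:
        raise GenioError(f"{path}: no BED records")
    return genes


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets; duplicate genes within a row are collapsed.

    Empty sets (after de-duplication) are retained so callers can flag them.
    """
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenioError(f"{path}:{lineno}: GMT line needs name and description fields")
            name = parts[0]
            genes = {g for g in parts[2:] if g}
            if name in pathways:
                raise GenioError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            pathways[name] = genes
    return pathways


def write_gmt(pathways: dict[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "na", *sorted(set(genes))]) + "\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value for one genotype table.

    Conditions on the observed allele counts: over all heterozygote counts
    of matching parity, P(het) is proportional to
    ``n! * 2**het / (n_AA! * n_Aa! * n_aa!)``.  The p-value sums the
    probabilities of every table no more probable than the observed one.
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise GenioError(f"negative genotype counts: {counts}")
    n = sum(counts)
    if n < 1:
        raise GenioError("empty genotype table")
    rare = 2 * min(n_hom_major, n_hom_minor) + n_het  # minor-allele copies
    # log-probability up to a constant shared by all tables with these allele counts
    def logp(het: int) -> float:
        hom_minor = (rare - het) // 2
        hom_major = n - het - hom_minor
        return (
            het * math.log(2.0)
            - math.lgamma(hom_major + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_minor + 1)
        )

    hets = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    logs = np.array([logp(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs_idx = (n_het - rare % 2) // 2
    p_obs = probs[obs_idx]
    # tolerance guards float ties between equally-likely tables
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

def qc_filter(
    g: GenotypeMatrix, t: QCThresholds
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter variants on MAF, missingness, HWE and imputation quality.

    MAF is the dosage-mean/2 folded to <= 0.5; HWE runs on hard calls
    (dosages rounded to the nearest integer).  Returns the retained matrix
    and a per-variant report with the metrics and failed rules.
    """
    if g.n_variants == 0:
        raise GenioError("empty genotype matrix")
    rows = []
    keep: list[int] = []
    for j, v in enumerate(g.variants):
        d = g.dosages[:, j]
        obs = d[np.isfinite(d)]
        miss_rate = 1.0 - obs.size / d.size
        if obs.size:
            af = float(obs.mean()) / 2.0
            maf = min(af, 1.0 - af)
            hard = np.rint(obs).astype(int)
            n_a1 = int((hard == 2).sum())
            n_het = int((hard == 1).sum())
            n_a2 = int((hard == 0).sum())
            # order hom classes so the third argument is the minor homozygote
            if af <= 0.5:
                hwe_p = hwe_exact_test(n_a2, n_het, n_a1)
            else:
                hwe_p = hwe_exact_test(n_a1, n_het, n_a2)
        else:
            maf = 0.0
            hwe_p = 1.0
        failed = []
        if not maf > t.min_maf:
            failed.append("maf")
        if not miss_rate < t.max_missing:
            failed.append("missing")
        if not hwe_p > t.min_hwe_p:
            failed.append("hwe")
        if v.info_r2 is not None and not v.info_r2 > t.min_info_r2:
            failed.append("info_r2")
        retained = not failed
        if retained:
            keep.append(j)
        rows.append(
            {
                "variant_id": v.variant_id,
                "maf": maf,
                "missing_rate": miss_rate,
                "hwe_p": hwe_p,
                "info_r2": v.info_r2,
                "retained": retained,
                "failed_rules": ",".join(failed),
            }
        )
    report = pd.DataFrame(rows)
    if not keep:
        raise GenioError("empty after QC: every variant failed at least one rule")
    return g.subset_variants(keep), report


# ---------------------------------------------------------------------------
# weight harmonization
# ---------------------------------------------------------------------------

def harmonize_weights(
    w: WeightSet,
    variants: Sequence[VariantRecord],
    drop_ambiguous: bool = True,
    allow_strand_flip: bool = True,
) -> tuple[WeightSet, pd.DataFrame]:
    """Align a weight file to the genotype allele encoding.

    Matching is by (chrom, pos).  If the file's effect allele equals the
    genotype's counted allele the weight is kept; if it equals the other
    allele the weight is negated; with ``allow_strand_flip`` the same
    logic is applied to the strand-complemented alleles.  A/T and C/G
    SNPs are dropped when ``drop_ambiguous``.  Returns the harmonized set
    (re-keyed to genotype variant ids and alleles) and a per-entry log.
    """
    by_pos: dict[tuple[str, int], VariantRecord] = {}
    for v in variants:
        if v.chrom is None or v.pos is None:
            raise GenioError(f"variant {v.variant_id} lacks coordinates; cannot harmonize")
        by_pos[(v.chrom, v.pos)] = v
    out_rows = []
    log_rows = []
    for row in w.entries.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        target = by_pos.get(key)
        ea, oa = str(row.effect_allele), str(row.other_allele)
        status = None
        weight = float(row.weight)
        if target is None:
            status = "unmatched"
        elif drop_ambiguous and target.is_ambiguous:
            status = "ambiguous"
        elif (ea, oa) == (target.allele_a1, target.allele_a2):
            status = "kept"
        elif (ea, oa) == (target.allele_a2, target.allele_a1):
            status, weight = "swapped", -weight
        elif allow_strand_flip and ea in _COMPLEMENT and oa in _COMPLEMENT:
            cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
            if (cea, coa) == (target.allele_a1, target.allele_a2):
                status = "strand_flipped"
            elif (cea, coa) == (target.allele_a2, target.allele_a1):
                status, weight = "strand_flipped_swapped", -weight
            else:
                status = "allele_mismatch"
        else:
            status = "allele_mismatch"
        log_rows.append(
            {"variant_id": row.variant_id, "chrom": key[0], "pos": key[1], "status": status}
        )
        if status in ("kept", "swapped", "strand_flipped", "strand_flipped_swapped"):
            out_rows.append(
                {
                    "variant_id": target.variant_id,
                    "chrom": target.chrom,
                    "pos": target.pos,
                    "effect_allele": target.allele_a1,
                    "other_allele": target.allele_a2,
                    "weight": weight,
                }
            )
    if not out_rows:
        raise GenioError(f"weight set {w.prs_name}: zero variants matched the genotype data")
    harmonized = WeightSet(w.prs_name, pd.DataFrame(out_rows))
    return harmonized, pd.DataFrame(log_rows)
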