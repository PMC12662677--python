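"""Readers and writers for the formats the pipeline touches.

Genotypes travel as plain VCF v4.x (diploid, unphased GT); phenotypes,
catalogs, SNP-to-gene annotations and candidate tables as TSV with named
headers; gene-set libraries as GMT. The two candidate tables published with
the study (heat-pattern and cold-pattern) ship with the package and are
exposed through :func:`load_candidate_fixture`.

Coordinates are 1-based throughout, as in VCF. Missing genotypes are stored
as ``nan`` in the dosage matrix; policy for handling them belongs to the
analysis modules, not the parsers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

AUTOSOMES = {str(c) for c in range(1, 23)}
RECOGNIZED_CHROMS = AUTOSOMES | {"X"}
CATALOG_CATEGORIES = ("cold_heat", "thyroid", "control")
PATTERNS = ("HP", "CP")


class ParseError(ValueError):
    """A file violated the expected format in a way we refuse to coerce."""


def _norm_chrom(label: str) -> str:
    c = label[3:] if label.lower().startswith("chr") else label
    if c not in RECOGNIZED_CHROMS:
        raise ParseError(f"unrecognized chromosome label {label!r}")
    return c


@dataclass(frozen=True)
class VariantMeta:
    """Identity and coordinates of one biallelic variant."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("variant id must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        _norm_chrom(self.chrom)


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with variant metadata.

    ``dosages`` is an ``(n_samples, n_variants)`` float array with entries in
    {0, 1, 2} and ``nan`` for missing genotypes.
    """

    samples: list[str]
    variants: list[VariantMeta]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be in {0, 1, 2}")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique")
        self._index = {vid: j for j, vid in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one variant id."""
        return self.dosages[:, self._index[snp_id]]

    def variant(self, snp_id: str) -> VariantMeta:
        return self.variants[self._index[snp_id]]

    def subset_variants(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._index[s] for s in snp_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in idx],
            dosages=self.dosages[:, idx].copy(),
        )


@dataclass(frozen=True)
class CatalogRecord:
    """One reported SNP-trait association from a GWAS-catalog-style table."""

    snp: str
    chrom: str
    pos: int
    trait: str
    category: str
    effect_allele: str
    reported_beta: float | None
    reported_p: float

    def __post_init__(self) -> None:
        if self.category not in CATALOG_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not (0.0 < self.reported_p <= 1.0):
            raise ValueError(f"reported_p must be in (0, 1], got {self.reported_p}")


@dataclass(frozen=True)
class CandidateRow:
    """One row of a published candidate-SNP table (replication columns)."""

    snp: str
    chrom: str
    pos: int
    trait: str
    gene: str
    pattern: str
    category: str
    a1: str
    a2: str
    maf: float
    beta: float
    se: float
    permutation_p: float

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if not (0.0 < self.permutation_p < 1.0):
            raise ValueError("permutation_p must be in (0, 1)")


@dataclass
class GeneSetLibrary:
    """Named gene sets plus the background they are tested against.

    When no explicit background is supplied it defaults to the union of all
    term genes.
    """

    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        for t, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {t!r} has an empty gene set")
        if self.background is not None:
            self.background = frozenset(self.background)
            for t, genes in self.terms.items():
                if not genes <= self.background:
                    raise ValueError(f"term {t!r} has genes outside the background")

    def effective_background(self) -> frozenset[str]:
        if self.background is not None:
            return self.background
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read a diploid GT-only VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are rejected unless ``split_multiallelic`` is set,
    in which case each alternate allele becomes its own variant whose dosage
    counts that allele.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantMeta] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vcf:
        alts = rec.ALT
        if len(alts) > 1 and not split_multiallelic:
            raise ParseError(
                f"multi-allelic record {rec.ID or rec.POS} at "
                f"{rec.CHROM}:{rec.POS}; set split_multiallelic to split"
            )
        gts = rec.genotypes
        alleles = np.empty((len(samples), 2), dtype=float)
        for i, gt in enumerate(gts):
            if len(gt) != 3:  # [a0, a1, phased]
                raise ParseError(
                    f"non-diploid genotype for sample {samples[i]} at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            a0, a1 = gt[0], gt[1]
            alleles[i] = (np.nan if a0 < 0 else a0, np.nan if a1 < 0 else a1)
        for k, alt in enumerate(alts, start=1):
            vid = rec.ID if rec.ID and len(alts) == 1 else f"{rec.ID or rec.CHROM + ':' + str(rec.POS)}" + (f"_{alt}" if len(alts) > 1 else "")
            if vid in seen:
                raise ParseError(f"duplicate variant id {vid!r}")
            seen.add(vid)
            dose = (alleles == k).sum(axis=1).astype(float)
            dose[np.isnan(alleles).any(axis=1)] = np.nan
            variants.append(
                VariantMeta(id=vid, chrom=_norm_chrom(rec.CHROM), pos=rec.POS,
                            ref=rec.REF, alt=alt)
            )
            columns.append(dose)
    vcf.close()
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF v4.2; unphased separator, missing as ``./.``."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in gm.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, v in enumerate(gm.variants):
            gts = [
                "./." if np.isnan(d) else _GT_STRINGS[d]
                for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _to_float(raw: str, what: str) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise ParseError(f"non-numeric {what}: {raw!r}") from exc


def read_catalog(path: str | Path) -> list[CatalogRecord]:
    """Read a GWAS-catalog-style reported-SNP table."""
    df = _read_tsv(
        path,
        ["snp", "chr", "pos", "trait", "category", "effect_allele", "reported_p"],
    )
    records = []
    for row in df.itertuples(index=False):
        beta_raw = getattr(row, "reported_beta", "")
        records.append(
            CatalogRecord(
                snp=row.snp,
                chrom=_norm_chrom(row.chr),
                pos=int(row.pos),
                trait=row.trait,
                category=row.category,
                effect_allele=row.effect_allele,
                reported_beta=None if beta_raw == "" else _to_float(beta_raw, "beta"),
                reported_p=_to_float(row.reported_p, "p value"),
            )
        )
    return records


def write_catalog(records: Iterable[CatalogRecord], path: str | Path) -> None:
    rows = [
        {
            "snp": r.snp,
            "chr": r.chrom,
            "pos": r.pos,
            "trait": r.trait,
            "category": r.category,
            "effect_allele": r.effect_allele,
            "reported_beta": "" if r.reported_beta is None else repr(r.reported_beta),
            "reported_p": repr(r.reported_p),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


PHENOTYPE_COLUMNS = ["sample", "cp_score", "hp_score", "age", "sex"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the per-sample phenotype/covariate table.

    Returns a DataFrame with columns sample, cp_score, hp_score, age, sex
    (sex coded 0/1). Missing covariates are rejected.
    """
    df = _read_tsv(path, PHENOTYPE_COLUMNS)
    out = pd.DataFrame({"sample": df["sample"]})
    for col in ("cp_score", "hp_score", "age"):
        out[col] = [_to_float(v, col) for v in df[col]]
    out["sex"] = [int(_to_float(v, "sex")) for v in df["sex"]]
    if out["sample"].duplicated().any():
        raise ParseError("duplicate sample ids in phenotype table")
    if not np.isfinite(out[["cp_score", "hp_score", "age"]].to_numpy()).all():
        raise ParseError("non-finite phenotype or covariate values")
    return out


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read a SNP-to-gene annotation TSV (columns ``snp``, ``gene``)."""
    df = _read_tsv(path, ["snp", "gene"])
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.snp in mapping and mapping[row.snp] != row.gene:
            raise ParseError(f"conflicting gene annotations for {row.snp}")
        mapping[row.snp] = row.gene
    return mapping


def write_annotation(mapping: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"snp": list(mapping), "gene": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT gene-set library (term TAB description TAB gene...)."""
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has < 3 fields")
            term, desc, *genes = fields
            genes = [g for g in genes if g]
            terms[term] = frozenset(genes)
            descriptions[term] = desc
    return GeneSetLibrary(terms=terms, descriptions=descriptions)


def write_gmt(lib: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in lib.terms.items():
            desc = lib.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Packaged candidate tables


def load_candidate_fixture(pattern: str) -> list[CandidateRow]:
    """Load the packaged heat-pattern (HP) or cold-pattern (CP) candidate table."""
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}")
    name = f"candidates_{pattern.lower()}.tsv"
    resource = importlib.resources.files("chp.data").joinpath(name)
    with importlib.resources.as_file(resource) as p:
        df = _read_tsv(p, [
            "snp", "chr", "pos", "reported_trait", "gene", "category",
            "a1", "a2", "maf", "beta", "se", "permutation_p",
        ])
    return [
        CandidateRow(
            snp=row.snp,
            chrom=row.chr,
            pos=int(row.pos),
            trait=row.reported_trait,
            gene=row.gene,
            pattern=pattern,
            category=row.category,
            a1=row.a1,
            a2=row.a2,
            maf=_to_float(row.maf, "maf"),
            beta=_to_float(row.beta, "beta"),
            se=_to_float(row.se, "se"),
            permutation_p=_to_float(row.permutation_p, "permutation p"),
        )
        for row in df.itertuples(index=False)
    ]
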