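"""Domain types, file readers/writers and validation for the pipeline.

Coordinates are 0-based half-open internally; VCF input/output converts at
the boundary.  BED input is already 0-based half-open and is taken as-is.

The genotype TSV dialect is one row per sample, one column per variant,
cells holding allele-pair strings (``AA``, ``AG`` ...) or ``.`` for missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

MISSING = -1  # genotype code for a missing call; never a valid genotype


class Trait(str, Enum):
    risk = "risk"
    survival = "survival"


class Status(str, Enum):
    case = "case"
    control = "control"


class BmiClass(str, Enum):
    normal = "normal"
    overweight = "overweight"
    obese = "obese"


class Placement(str, Enum):
    in_site = "in_site"
    flank = "flank"


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant; ``pos`` is 0-based."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"variant {self.id}: negative position {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id}: ref equals alt ({self.ref})")


@dataclass(frozen=True)
class GwasHit:
    variant_id: str
    trait: Trait
    p_value: float
    study: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"GWAS hit {self.variant_id}: p-value {self.p_value} outside (0, 1]"
            )


@dataclass
class HaplotypePanel:
    """Phased allele matrix: rows = variants, columns = chromosomes (2N)."""

    variants: list[VariantRecord]
    alleles: np.ndarray  # shape (n_variants, 2 * n_individuals), entries {0, 1}
    populations: list[str] = field(default_factory=list)  # one label per individual

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != len(self.variants):
            raise ValueError("allele matrix shape inconsistent with variant list")
        if self.alleles.shape[1] % 2 != 0:
            raise ValueError("chromosome count must be even (two per individual)")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele matrix entries must be 0 or 1")
        keys = [(v.chrom, v.pos) for v in self.variants]
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("variants must be strictly increasing by (chrom, pos)")

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[1]

    def index_of(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.id == variant_id:
                return i
        raise KeyError(variant_id)


@dataclass
class GenotypeMatrix:
    """Unphased genotype codes: 0 ref-hom, 1 het, 2 alt-hom, MISSING."""

    samples: list[str]
    variants: list[VariantRecord]
    codes: np.ndarray  # shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.variants)):
            raise ValueError("genotype matrix shape inconsistent with labels")
        if self.codes.size and not np.isin(self.codes, (0, 1, 2, MISSING)).all():
            raise ValueError("genotype codes must be 0/1/2 or missing")

    def index_of(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.id == variant_id:
                return i
        raise KeyError(variant_id)

    def column(self, variant: int | str) -> np.ndarray:
        j = variant if isinstance(variant, int) else self.index_of(variant)
        return self.codes[:, j]


def classify_bmi(bmi: float) -> BmiClass:
    """BMI class with the conventional cutoffs: <25 normal, [25, 30) overweight, >=30 obese."""
    if bmi >= 30.0:
        return BmiClass.obese
    if bmi >= 25.0:
        return BmiClass.overweight
    return BmiClass.normal


@dataclass
class SampleRecord:
    sample_id: str
    status: Status
    bmi: float
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bmi < 18.5:
            raise ValueError(
                f"sample {self.sample_id}: BMI {self.bmi} below inclusion cutoff 18.5"
            )

    @property
    def bmi_class(self) -> BmiClass:
        return classify_bmi(self.bmi)


@dataclass(frozen=True)
class BindingSite:
    """miRNA binding interval on a gene; [start, end) half-open, 0-based."""

    gene: str
    mirna: str
    chrom: str
    start: int
    end: int
    strand: str
    source: str = "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"site {self.mirna}:{self.gene} {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"site {self.mirna}:{self.gene}: invalid strand {self.strand!r}")


@dataclass
class PathwaySet:
    name: str
    source: str
    genes: set[str]
    inflammatory: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r}: empty gene set")


@dataclass
class PipelineConfig:
    """Thresholds and knobs for the prioritization + association pipeline."""

    gwas_p_threshold: float = 1e-6
    r2_threshold: float = 0.6
    proxy_window_bp: int = 1_000_000
    flank_nt: int = 25
    alpha: float = 0.05
    ci_level: float = 0.95
    min_stratum_size: int = 10
    covariates: tuple[str, ...] = (
        "age",
        "sex",
        "diabetes",
        "family_cancer_history",
        "smoking",
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.flank_nt < 0:
            raise ValueError("flank_nt must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "covariates" in data:
            data["covariates"] = tuple(data["covariates"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_haplotype_panel(path: str | Path) -> HaplotypePanel:
    """Read a phased biallelic VCF into a :class:`HaplotypePanel`.

    Raises on any unphased GT or multiallelic record, naming the offender.
    Population labels are taken from a ``POP`` entry in the header line
    ``##SAMPLE=<ID=...,POP=...>`` when present, else left empty.
    """
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        pops = _sample_populations(vcf.header, sample_names)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(
                    f"record {rec.id or rec.chrom + ':' + str(rec.pos)}: "
                    "multiallelic records are not supported"
                )
            row = np.empty(2 * len(sample_names), dtype=np.int8)
            for i, name in enumerate(sample_names):
                call = rec.samples[name]
                if not call.phased:
                    raise ValueError(
                        f"record {rec.id or rec.chrom + ':' + str(rec.pos)}, "
                        f"sample {name}: genotype is not phased"
                    )
                gt = call["GT"]
                if len(gt) != 2 or any(a is None for a in gt):
                    raise ValueError(
                        f"record {rec.id}, sample {name}: incomplete phased genotype"
                    )
                row[2 * i], row[2 * i + 1] = gt
            variants.append(
                VariantRecord(
                    id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.start,  # pysam .start is already 0-based
                    ref=rec.ref,
                    alt=rec.alts[0],
                )
            )
            columns.append(row)
    alleles = np.vstack(columns) if columns else np.empty((0, 2 * len(sample_names)), np.int8)
    return HaplotypePanel(variants=variants, alleles=alleles, populations=pops)


def _sample_populations(header: pysam.VariantHeader, names: Sequence[str]) -> list[str]:
    pops = {}
    for rec in header.records:
        if rec.key == "SAMPLE":
            rid = rec.get("ID")
            if rid:
                pops[rid] = rec.get("POP", "")
    return [pops.get(n, "") for n in names]


def write_haplotype_panel(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as an uncompressed phased VCF."""
    n_ind = panel.n_chromosomes // 2
    names = [f"HG{i:05d}" for i in range(n_ind)]
    chroms = sorted({v.chrom for v in panel.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, pop in zip(names, panel.populations or [""] * n_ind):
            fh.write(f"##SAMPLE=<ID={name},POP={pop}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        for v, row in zip(panel.variants, panel.alleles):
            gts = "\t".join(f"{row[2 * i]}|{row[2 * i + 1]}" for i in range(n_ind))
            fh.write(f"{v.chrom}\t{v.pos + 1}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read unphased genotypes from VCF or allele-pair TSV (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_genotypes_vcf(path)
    return _read_genotypes_tsv(path)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(f"record {rec.id}: multiallelic records are not supported")
            col = np.empty(len(samples), dtype=np.int8)
            for i, name in enumerate(samples):
                gt = rec.samples[name]["GT"]
                if gt is None or any(a is None for a in gt):
                    col[i] = MISSING
                else:
                    col[i] = sum(gt)
            variants.append(
                VariantRecord(rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom, rec.start,
                              rec.ref, rec.alts[0])
            )
            cols.append(col)
    codes = np.column_stack(cols) if cols else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(samples=samples, variants=variants, codes=codes)


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    """TSV dialect: header ``sample_id  <rsid>:<chrom>:<pos1>:<ref>:<alt> ...``;
    cells are allele pairs (``AA``, ``AG``) or ``.``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    variants = []
    for col in df.columns[1:]:
        parts = col.split(":")
        if len(parts) != 5:
            raise ValueError(f"{path}: malformed variant column {col!r}")
        rsid, chrom, pos1, ref, alt = parts
        variants.append(VariantRecord(rsid, chrom, int(pos1) - 1, ref, alt))
    samples = df["sample_id"].tolist()
    codes = np.full((len(samples), len(variants)), MISSING, dtype=np.int8)
    for j, (col, v) in enumerate(zip(df.columns[1:], variants)):
        for i, cell in enumerate(df[col].astype(str)):
            codes[i, j] = _code_allele_pair(cell, v)
    return GenotypeMatrix(samples=samples, variants=variants, codes=codes)


def _code_allele_pair(cell: str, v: VariantRecord) -> int:
    if cell in (".", "./.", "nan", ""):
        return MISSING
    if len(cell) != 2:
        raise ValueError(f"variant {v.id}: unknown genotype symbol {cell!r}")
    n_alt = 0
    for a in cell:
        if a == v.alt:
            n_alt += 1
        elif a != v.ref:
            raise ValueError(
                f"variant {v.id}: allele {a!r} in {cell!r} matches neither "
                f"ref {v.ref} nor alt {v.alt}"
            )
    return n_alt


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the allele-pair TSV dialect (lossless round-trip with read_genotypes)."""
    header = ["sample_id"] + [
        f"{v.id}:{v.chrom}:{v.pos + 1}:{v.ref}:{v.alt}" for v in gm.variants
    ]
    strings = {0: None, 1: None, 2: None}
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, s in enumerate(gm.samples):
            cells = []
            for j, v in enumerate(gm.variants):
                c = gm.codes[i, j]
                if c == MISSING:
                    cells.append(".")
                elif c == 0:
                    cells.append(v.ref + v.ref)
                elif c == 1:
                    cells.append(v.ref + v.alt)
                else:
                    cells.append(v.alt + v.alt)
            fh.write(s + "\t" + "\t".join(cells) + "\n")


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Sample/phenotype TSV: sample_id, status, bmi, then covariate columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "status", "bmi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    covariate_cols = [c for c in df.columns if c not in required]
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                status=Status(row["status"]),
                bmi=float(row["bmi"]),
                covariates={c: float(row[c]) for c in covariate_cols},
            )
        )
    return records


def write_samples(records: Iterable[SampleRecord], path: str | Path) -> None:
    records = list(records)
    cov_names = sorted({k for r in records for k in r.covariates})
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "status": r.status.value, "bmi": r.bmi}
        row.update({c: r.covariates.get(c, "") for c in cov_names})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> list[BindingSite]:
    """BED-like site file: chrom start end mirna|gene score strand [source]."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            source = fields[6] if len(fields) > 6 else "other"
            try:
                mirna, gene = name.split("|", 1)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: name field must be 'mirna|gene', got {name!r}"
                ) from None
            start_i, end_i = int(start), int(end)
            if start_i >= end_i:
                raise ValueError(f"{path}:{lineno}: start {start_i} >= end {end_i}")
            sites.append(BindingSite(gene, mirna, chrom, start_i, end_i, strand, source))
    return sites


def write_sites(sites: Iterable[BindingSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.mirna}|{s.gene}\t.\t{s.strand}\t{s.source}\n"
            )


def read_pathways(path: str | Path) -> list[PathwaySet]:
    """Pathway TSV: pathway, source, gene, inflammatory. Duplicate rows deduplicated."""
    df = pd.read_csv(path, sep="\t")
    required = {"pathway", "source", "gene", "inflammatory"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df.duplicated(subset=["pathway", "gene"]).any():
        warnings.warn(f"{path}: duplicate pathway/gene pairs deduplicated", stacklevel=2)
        df = df.drop_duplicates(subset=["pathway", "gene"])
    out = []
    for (name, source, infl), grp in df.groupby(["pathway", "source", "inflammatory"]):
        out.append(
            PathwaySet(
                name=name,
                source=source,
                genes=set(grp["gene"].astype(str)),
                inflammatory=bool(infl),
            )
        )
    return out


def write_pathways(pathways: Iterable[PathwaySet], path: str | Path) -> None:
    rows = [
        {"pathway": p.name, "source": p.source, "gene": g, "inflammatory": p.inflammatory}
        for p in pathways
        for g in sorted(p.genes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gwas_hits(path: str | Path) -> list[GwasHit]:
    """GWAS hit TSV: variant_id, trait, p_value, study."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "trait", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        GwasHit(
            variant_id=str(r["variant_id"]),
            trait=Trait(r["trait"]),
            p_value=float(r["p_value"]),
            study=str(r.get("study", "")),
        )
        for r in df.to_dict("records")
    ]


def write_gwas_hits(hits: Iterable[GwasHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"variant_id": h.variant_id, "trait": h.trait.value,
             "p_value": h.p_value, "study": h.study}
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)
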