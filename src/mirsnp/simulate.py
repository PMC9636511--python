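"""Synthetic study data with known ground truth.

Everything the pipeline consumes can be generated here: a phased haplotype
panel with controlled pairwise LD, a case-control cohort with genotype
effects injected through a logistic disease model, and a planted
binding-site / pathway / GWAS-hit fixture for the prioritization cascade.

LD construction: a proxy column is made by copying its parent column and,
independently per chromosome with probability ``e``, redrawing the allele
from Bernoulli(MAF).  The allele correlation is then exactly ``1 - e`` in
expectation, so ``e = 1 - sqrt(r2_target)`` hits any feasible target when
both loci share a MAF.  This reproduces the pairwise LD the analyses need
without recombination maps or coalescent machinery.

Cohort defaults mirror a mid-sized case-control study of colorectal cancer
and obesity: 215 cases + 215 controls, age ~ Normal(56, 11) years, ~47%
male, BMI split roughly 27/44/29% across normal/overweight/obese classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .io_model import (
    BindingSite,
    GenotypeMatrix,
    GwasHit,
    HaplotypePanel,
    MISSING,
    PathwaySet,
    SampleRecord,
    Status,
    Trait,
    VariantRecord,
)

__all__ = ["SimulationSpec", "simulate_panel", "simulate_cohort", "simulate_targetome"]


@dataclass
class CovariateSpec:
    """Distributions and logistic coefficients of the adjustment covariates."""

    age_mean: float = 56.0
    age_sd: float = 11.0
    sex_male_frac: float = 0.47
    diabetes_frac: float = 0.12
    family_history_frac: float = 0.23
    smoking_frac: float = 0.20
    # log-odds effects on case status
    betas: dict[str, float] = field(default_factory=lambda: {
        "age": 0.02, "sex": 0.3, "diabetes": 0.5,
        "family_cancer_history": 0.4, "smoking": 0.4,
    })


@dataclass
class SimulationSpec:
    n_individuals: int = 430
    n_variants: int = 2
    mafs: Sequence[float] | None = None  # default: uniform in maf_range
    maf_range: tuple[float, float] = (0.2, 0.5)
    target_ld: Sequence[tuple[int, int, float]] = ()  # (parent, child, r2)
    case_fraction: float = 0.5
    # per-variant effects: (variant index, model, odds ratio)
    effects: Sequence[tuple[int, str, float]] = ()
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    bmi_fractions: tuple[float, float, float] = (0.27, 0.44, 0.29)  # normal/over/obese
    missing_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")
        if not math.isclose(sum(self.bmi_fractions), 1.0, abs_tol=1e-9):
            raise ValueError("bmi_fractions must sum to 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for _, _, r2 in self.target_ld:
            if not (0.0 <= r2 <= 1.0):
                raise ValueError(f"target r2 {r2} outside [0, 1]")


def simulate_panel(spec: SimulationSpec, n_chromosomes: int | None = None) -> HaplotypePanel:
    """Phased haplotype panel with the requested MAFs and pairwise LD.

    LD pairs are built child-from-parent by copy-with-redraw (see module
    docstring); the child's MAF is forced equal to its parent's, since the
    redraw construction attains ``r2`` exactly only at matched MAFs.  A
    target of 1 duplicates the column verbatim.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_chrom = n_chromosomes if n_chromosomes is not None else 2 * spec.n_individuals
    if n_chrom % 2:
        raise ValueError("n_chromosomes must be even")
    if spec.mafs is not None:
        mafs = np.asarray(list(spec.mafs), dtype=float)
        if len(mafs) != spec.n_variants:
            raise ValueError("mafs length must equal n_variants")
    else:
        mafs = rng.uniform(*spec.maf_range, size=spec.n_variants)

    children = {child: (parent, r2) for parent, child, r2 in spec.target_ld}
    for child, (parent, _) in children.items():
        if parent in children:
            raise ValueError("chained LD targets are not supported")

    alleles = np.zeros((spec.n_variants, n_chrom), dtype=np.int8)
    for j in range(spec.n_variants):
        if j in children:
            continue
        alleles[j] = rng.random(n_chrom) < mafs[j]
    for child, (parent, r2) in children.items():
        maf = mafs[parent]
        mafs[child] = maf
        if r2 >= 1.0:
            alleles[child] = alleles[parent]
            continue
        e = 1.0 - math.sqrt(r2)
        redraw = rng.random(n_chrom) < e
        fresh = (rng.random(n_chrom) < maf).astype(np.int8)
        alleles[child] = np.where(redraw, fresh, alleles[parent])

    variants = [
        VariantRecord(f"rs{1000 + j}", "chr1", 1000 + 5000 * j, "A", "G")
        for j in range(spec.n_variants)
    ]
    pops = ["SIM"] * (n_chrom // 2)
    return HaplotypePanel(variants=variants, alleles=alleles, populations=pops)


_ENCODE = {
    "dominant": lambda g: (g >= 1).astype(float),
    "recessive": lambda g: (g == 2).astype(float),
    "overdominant": lambda g: (g == 1).astype(float),
    "allelic": lambda g: g.astype(float),  # additive per-allele
    "additive": lambda g: g.astype(float),
}


def simulate_cohort(
    spec: SimulationSpec, panel: HaplotypePanel
) -> tuple[GenotypeMatrix, list[SampleRecord], dict]:
    """Draw a case-control cohort from a phased panel.

    Genotypes pair two panel chromosomes per individual (with replacement).
    Case status follows logistic(b0 + genotype effects + covariate effects);
    the intercept b0 is solved numerically so the expected case fraction
    matches the spec.  Returns the matrix, the sample table, and a
    ground-truth dict of the planted parameters.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    n = spec.n_individuals
    n_chrom = panel.n_chromosomes

    ha = rng.integers(0, n_chrom, size=n)
    hb = rng.integers(0, n_chrom, size=n)
    codes = (panel.alleles[:, ha] + panel.alleles[:, hb]).T.astype(np.int8)  # samples x variants

    cov = spec.covariates
    age = rng.normal(cov.age_mean, cov.age_sd, size=n)
    sex = (rng.random(n) < cov.sex_male_frac).astype(float)
    diabetes = (rng.random(n) < cov.diabetes_frac).astype(float)
    famhist = (rng.random(n) < cov.family_history_frac).astype(float)
    smoking = (rng.random(n) < cov.smoking_frac).astype(float)

    eta = (
        cov.betas["age"] * (age - cov.age_mean)
        + cov.betas["sex"] * sex
        + cov.betas["diabetes"] * diabetes
        + cov.betas["family_cancer_history"] * famhist
        + cov.betas["smoking"] * smoking
    )
    for idx, model, orr in spec.effects:
        if orr <= 0:
            raise ValueError("odds ratios must be positive")
        eta = eta + math.log(orr) * _ENCODE[model](codes[:, idx])

    def mean_prob(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))))

    lo, hi = -30.0, 30.0
    if not (mean_prob(lo) <= spec.case_fraction <= mean_prob(hi)):
        raise ValueError("requested case_fraction unreachable within intercept bounds")
    b0 = brentq(lambda b: mean_prob(b) - spec.case_fraction, lo, hi)
    prob = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    is_case = rng.random(n) < prob

    # BMI: uniform within each class band, class drawn from the spec mixture
    klass = rng.choice(3, size=n, p=spec.bmi_fractions)
    bmi = np.where(
        klass == 0, rng.uniform(18.5, 25.0, n),
        np.where(klass == 1, rng.uniform(25.0, 30.0, n), rng.uniform(30.0, 45.0, n)),
    )

    if spec.missing_rate > 0:
        drop = rng.random(codes.shape) < spec.missing_rate
        codes = np.where(drop, MISSING, codes).astype(np.int8)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    samples = [
        SampleRecord(
            sample_id=sample_ids[i],
            status=Status.case if is_case[i] else Status.control,
            bmi=float(bmi[i]),
            covariates={
                "age": float(age[i]), "sex": float(sex[i]),
                "diabetes": float(diabetes[i]),
                "family_cancer_history": float(famhist[i]),
                "smoking": float(smoking[i]),
            },
        )
        for i in range(n)
    ]
    gm = GenotypeMatrix(samples=sample_ids, variants=list(panel.variants), codes=codes)
    truth = {
        "intercept": b0,
        "effects": [
            {"variant": panel.variants[idx].id, "model": model, "odds_ratio": orr}
            for idx, model, orr in spec.effects
        ],
        "case_fraction_realized": float(np.mean(is_case)),
        "covariate_betas": dict(cov.betas),
    }
    return gm, samples, truth


def simulate_targetome(
    spec: SimulationSpec,
    panel: HaplotypePanel | None = None,
) -> tuple[list[BindingSite], list[PathwaySet], list[GwasHit], dict]:
    """Planted fixture for the prioritization cascade.

    Builds binding sites, pathways and GWAS hits around a panel such that
    the ground truth of every filtering step is known: which hits pass the
    p-value screen, which variants are in-site vs flank vs outside, and
    which genes survive the inflammatory-pathway filter.  Returns the three
    input lists plus a truth dict naming the expected survivors.
    """
    panel = panel if panel is not None else simulate_panel(spec)
    variants = panel.variants
    if len(variants) < 1:
        raise ValueError("panel must contain at least one variant")

    sites: list[BindingSite] = []
    truth_placement: dict[str, str] = {}
    genes = ["LAMC1", "GNB3", "XYZ1"]  # XYZ1 planted outside inflammatory pathways
    for j, v in enumerate(variants):
        gene = genes[j % len(genes)]
        mirna = f"miR-{500 + j}"
        kind = j % 3
        if kind == 0:  # inside the 7-mer site
            site = BindingSite(gene, mirna, v.chrom, v.pos - 3, v.pos + 4, "-", "targetscan")
            truth_placement[v.id] = "in_site"
        elif kind == 1:  # exactly on the upstream flank boundary
            site = BindingSite(gene, mirna, v.chrom, v.pos + 25, v.pos + 32, "-", "starbase")
            truth_placement[v.id] = "flank"
        else:  # outside site and flank
            site = BindingSite(gene, mirna, v.chrom, v.pos + 100, v.pos + 107, "+", "microrna_org")
            truth_placement[v.id] = "outside"
        sites.append(site)

    pathways = [
        PathwaySet("Inflammatory Response Pathway", "WikiPathways", {"LAMC1"}, True),
        PathwaySet("ERK Signaling SuperPath", "PathCards", {"LAMC1", "GNB3"}, True),
        PathwaySet("PI3K/Akt Signaling", "KEGG", {"LAMC1", "GNB3"}, True),
        PathwaySet("Housekeeping", "KEGG", {"XYZ1"}, False),
    ]
    hits = [
        GwasHit(v.id, Trait.risk, 1e-8, study=f"study_{j}")
        for j, v in enumerate(variants)
    ]
    inflammatory_genes = {"LAMC1", "GNB3"}
    survivors = sorted(
        v.id for j, v in enumerate(variants)
        if truth_placement[v.id] != "outside" and genes[j % len(genes)] in inflammatory_genes
    )
    truth = {
        "placement": truth_placement,
        "inflammatory_genes": sorted(inflammatory_genes),
        "expected_survivors": survivors,
    }
    return sites, pathways, hits, truth
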