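"""Case-control statistics: HWE, genetic-model contrasts, odds ratios,
logistic adjustment, and cumulative two-locus genotype/haplotype tables.

Genetic-model conventions (exposure x status 2x2 tables, cells a,b;c,d =
exposed-case, unexposed-case; exposed-control, unexposed-control):

* dominant      carriers (het + alt-hom) vs ref-hom
* recessive     alt-hom vs (ref-hom + het)
* overdominant  het vs both homozygotes
* codominant    one genotype pair at a time (three pairings)
* allelic       alt vs ref allele counts (2n denominators)

The first-listed genotype class of each model is the reference (OR = 1)
row.  Crude ORs are cross-products with Woolf confidence intervals; a zero
cell triggers the Haldane-Anscombe +0.5 correction and is flagged.
Adjusted ORs come from maximum-likelihood logistic regression with Wald
intervals and p-values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from . import ld as ldmod
from .io_model import (
    MISSING,
    BmiClass,
    GenotypeMatrix,
    PipelineConfig,
    SampleRecord,
    Status,
)

__all__ = [
    "GenotypeCounts",
    "HWEResult",
    "GeneticModelTable",
    "AssociationResult",
    "MODELS",
    "genotype_counts",
    "hwe_test",
    "allele_counts",
    "model_table",
    "crude_or",
    "logistic_fit",
    "adjusted_or",
    "fisher_exact",
    "pearson_chi2",
    "cumulative_genotypes",
    "run_association_suite",
    "stratum_mask",
]


@dataclass(frozen=True)
class GenotypeCounts:
    n_ref_hom: int
    n_het: int
    n_alt_hom: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ref_hom, self.n_het, self.n_alt_hom, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_alt_hom

    @property
    def monomorphic(self) -> bool:
        nonzero = [c > 0 for c in (self.n_ref_hom, self.n_het, self.n_alt_hom)]
        return sum(nonzero) <= 1 and self.n_het == 0


def genotype_counts(codes: np.ndarray) -> GenotypeCounts:
    codes = np.asarray(codes)
    return GenotypeCounts(
        int((codes == 0).sum()), int((codes == 1).sum()),
        int((codes == 2).sum()), int((codes == MISSING).sum()),
    )


@dataclass
class HWEResult:
    chi2: float
    df: int
    p: float
    expected: tuple[float, float, float]
    allele_freq: float  # alt-allele frequency
    defined: bool = True
    note: str = ""


def hwe_test(counts: GenotypeCounts) -> HWEResult:
    """Chi-square goodness-of-fit test against Hardy-Weinberg proportions.

    No continuity correction is applied.  A monomorphic variant yields a
    flagged undefined result rather than an exception or NaN.
    """
    n = counts.total
    if n < 1:
        raise ValueError("HWE test requires at least one genotyped sample")
    if counts.monomorphic:
        return HWEResult(
            chi2=float("nan"), df=1, p=float("nan"),
            expected=(float(counts.n_ref_hom), float(counts.n_het), float(counts.n_alt_hom)),
            allele_freq=(2 * counts.n_alt_hom + counts.n_het) / (2 * n),
            defined=False, note="monomorphic variant: HWE undefined",
        )
    p_ref = (2 * counts.n_ref_hom + counts.n_het) / (2 * n)
    q = 1.0 - p_ref
    expected = (n * p_ref * p_ref, 2 * n * p_ref * q, n * q * q)
    observed = (counts.n_ref_hom, counts.n_het, counts.n_alt_hom)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HWEResult(
        chi2=chi2, df=1, p=float(st.chi2.sf(chi2, 1)),
        expected=expected, allele_freq=q,
    )


def allele_counts(counts: GenotypeCounts) -> tuple[int, int]:
    """(ref allele count, alt allele count) over genotyped samples."""
    if counts.total == 0:
        raise ValueError("no genotyped samples")
    return (
        2 * counts.n_ref_hom + counts.n_het,
        2 * counts.n_alt_hom + counts.n_het,
    )


MODELS = ("dominant", "recessive", "overdominant", "codominant", "allelic")

# codominant pairings in Tables-style row order: (reference class, contrast class)
CODOMINANT_PAIRS = (("ref_hom", "alt_hom"), ("ref_hom", "het"), ("het", "alt_hom"))


@dataclass
class GeneticModelTable:
    """2x2 exposure x status table for one genetic-model contrast.

    ``table`` rows are (case, control); columns (exposed, reference).
    """

    model: str
    table: np.ndarray
    label: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.shape != (2, 2):
            raise ValueError("model table must be 2x2")


def _model_cells(c: GenotypeCounts, model: str,
                 pair: tuple[str, str] | None = None) -> tuple[int, int]:
    """(exposed, reference) cell counts for one group under a model."""
    by_class = {"ref_hom": c.n_ref_hom, "het": c.n_het, "alt_hom": c.n_alt_hom}
    if model == "dominant":
        return c.n_het + c.n_alt_hom, c.n_ref_hom
    if model == "recessive":
        return c.n_alt_hom, c.n_ref_hom + c.n_het
    if model == "overdominant":
        return c.n_het, c.n_ref_hom + c.n_alt_hom
    if model == "allelic":
        ref, alt = allele_counts(c)
        return alt, ref
    if model == "codominant":
        if pair is None:
            raise ValueError("codominant model requires a genotype pair")
        ref_class, exp_class = pair
        return by_class[exp_class], by_class[ref_class]
    raise ValueError(f"unknown genetic model {model!r}")


def model_table(case: GenotypeCounts, control: GenotypeCounts, model: str,
                pair: tuple[str, str] | None = None) -> GeneticModelTable:
    """Build the 2x2 exposure x status table for a genetic model."""
    if case.total == 0 or control.total == 0:
        raise ValueError("both groups must contain genotyped samples")
    a, b = _model_cells(case, model, pair)
    c, d = _model_cells(control, model, pair)
    label = model if pair is None else f"{model}:{pair[1]}_vs_{pair[0]}"
    table = np.array([[a, b], [c, d]])
    degenerate = bool((table.sum(axis=0) == 0).any())
    return GeneticModelTable(model=model, table=table, label=label, degenerate=degenerate)


@dataclass
class AssociationResult:
    model: str
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    adjusted: bool
    covariates: list[str] = field(default_factory=list)
    n_used: int = 0
    corrected: bool = False  # Haldane-Anscombe +0.5 applied
    defined: bool = True
    note: str = ""


def crude_or(table: np.ndarray | GeneticModelTable, ci_level: float = 0.95,
             model: str = "") -> AssociationResult:
    """Cross-product odds ratio with Woolf (log) confidence interval.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction (flagged);
    a fully empty row or column leaves the OR undefined.
    """
    if isinstance(table, GeneticModelTable):
        model = model or table.label
        table = table.table
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return AssociationResult(
            model=model, or_point=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), p=float("nan"), adjusted=False,
            n_used=int(t.sum()), defined=False,
            note="zero margin: odds ratio undefined",
        )
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    or_point = (a * d) / (b * c)
    z = st.norm.ppf(0.5 + ci_level / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(or_point) - z * se)
    ci_high = math.exp(math.log(or_point) + z * se)
    wald = math.log(or_point) / se
    p = 2 * st.norm.sf(abs(wald))
    return AssociationResult(
        model=model, or_point=or_point, ci_low=ci_low, ci_high=ci_high,
        p=p, adjusted=False, n_used=int(round(t.sum() - (2.0 if corrected else 0.0))),
        corrected=corrected,
    )


@dataclass
class LogisticFit:
    params: np.ndarray
    cov: np.ndarray
    names: list[str]
    converged: bool
    n_used: int
    separation: bool = False

    def wald(self, name: str, ci_level: float = 0.95) -> tuple[float, float, float, float]:
        """(OR, ci_low, ci_high, p) for one coefficient."""
        i = self.names.index(name)
        beta = self.params[i]
        se = math.sqrt(self.cov[i, i])
        z = st.norm.ppf(0.5 + ci_level / 2)
        p = 2 * st.norm.sf(abs(beta / se)) if se > 0 else float("nan")
        return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se), p


def logistic_fit(outcome: np.ndarray, design: np.ndarray | pd.DataFrame,
                 names: Sequence[str] | None = None,
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS/Newton via statsmodels).

    ``design`` must NOT contain an intercept column; one is added.  Complete
    separation is flagged (``separation=True``) instead of reporting a
    runaway estimate; rank deficiency raises, naming the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant")
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X]))
    if rank < X.shape[1] + 1:
        bad = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient (collinear: {bad})")
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, Xc)
        try:
            res = model.fit(disp=0, method="newton", tol=tol, maxiter=max_iter)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            # Newton diverges under (quasi-)complete separation; flag it
            # rather than reporting a runaway estimate.
            k = Xc.shape[1]
            return LogisticFit(
                params=np.full(k, np.nan), cov=np.full((k, k), np.nan),
                names=["const"] + names, converged=False,
                n_used=len(y), separation=True,
            )
    params = np.asarray(res.params)
    separation = bool(np.any(np.abs(params[1:]) > 15))
    return LogisticFit(
        params=params, cov=np.asarray(res.cov_params()),
        names=["const"] + names, converged=bool(res.mle_retvals["converged"]),
        n_used=len(y), separation=separation,
    )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    bad = []
    base = np.column_stack([np.ones(X.shape[0])])
    for j in range(X.shape[1]):
        trial = np.column_stack([base, X[:, j]])
        if np.linalg.matrix_rank(trial) == base.shape[1]:
            bad.append(names[j])
        else:
            base = trial
    return bad


def adjusted_or(outcome: np.ndarray, exposure: np.ndarray,
                covariates: pd.DataFrame | None = None,
                ci_level: float = 0.95, model: str = "") -> AssociationResult:
    """Covariate-adjusted odds ratio for a binary/continuous exposure."""
    if covariates is not None and len(covariates.columns):
        design = pd.concat(
            [pd.Series(exposure, name="exposure", index=covariates.index), covariates],
            axis=1,
        )
        cov_names = list(covariates.columns)
    else:
        design = pd.DataFrame({"exposure": np.asarray(exposure)})
        cov_names = []
    fit = logistic_fit(np.asarray(outcome), design)
    if fit.separation:
        return AssociationResult(
            model=model, or_point=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), p=float("nan"), adjusted=bool(cov_names),
            covariates=cov_names, n_used=fit.n_used, defined=False,
            note="complete separation detected",
        )
    or_point, lo, hi, p = fit.wald("exposure", ci_level)
    return AssociationResult(
        model=model, or_point=or_point, ci_low=lo, ci_high=hi, p=p,
        adjusted=bool(cov_names), covariates=cov_names, n_used=fit.n_used,
    )


def fisher_exact(table: np.ndarray) -> tuple[float, float]:
    """(two-sided, one-sided) Fisher exact p for a 2x2 table.

    Two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed one;
    the one-sided p is the smaller tail.
    """
    t = np.asarray(table, dtype=np.int64)
    if (t < 0).any():
        raise ValueError("table cells must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0, 1.0
    two = float(st.fisher_exact(t, alternative="two-sided")[1])
    less = float(st.fisher_exact(t, alternative="less")[1])
    greater = float(st.fisher_exact(t, alternative="greater")[1])
    return two, min(less, greater)


def pearson_chi2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) for a 2xk table."""
    t = np.asarray(table, dtype=float)
    expected = st.contingency.expected_freq(t)
    if (expected <= 0).any():
        raise ValueError("zero expected count: use fisher_exact instead")
    chi2, p, df, _ = st.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# cumulative genotypes / haplotypes
# ---------------------------------------------------------------------------

GENOTYPE_LABELS = ("ref_hom", "het", "alt_hom")


@dataclass
class CumulativeGenotypeTable:
    """Joint two-locus genotype frequencies and EM haplotype frequencies
    per sample group, with pairwise group comparisons per genotype class."""

    variant_pair: tuple[str, str]
    genotype_freqs: pd.DataFrame  # index: 9 joint classes; columns: groups
    hap_freqs: pd.DataFrame  # index: 4 haplotypes; columns: groups
    group_sizes: dict[str, int]
    comparisons: pd.DataFrame  # columns: group_a, group_b, genotype, p, test
    excluded_groups: list[str] = field(default_factory=list)


def _joint_labels(v1_alleles: tuple[str, str], v2_alleles: tuple[str, str]) -> list[str]:
    def geno(alleles: tuple[str, str], code: int) -> str:
        r, a = alleles
        return (r + r, r + a, a + a)[code]

    return [
        f"{geno(v1_alleles, i)}/{geno(v2_alleles, j)}"
        for i in range(3)
        for j in range(3)
    ]


def cumulative_genotypes(
    genotypes: GenotypeMatrix,
    v1: int | str,
    v2: int | str,
    groups: dict[str, np.ndarray],
    expected_min: float = 5.0,
) -> CumulativeGenotypeTable:
    """Joint genotype and haplotype frequencies at two loci across groups.

    ``groups`` maps group label -> boolean sample mask.  Frequencies use
    complete cases (samples typed at both loci).  Per genotype class and
    group pair, a 2x2 presence/absence table is tested by Pearson chi-square,
    falling back to Fisher's exact test when any expected count is below
    ``expected_min``.
    """
    i1 = v1 if isinstance(v1, int) else genotypes.index_of(v1)
    i2 = v2 if isinstance(v2, int) else genotypes.index_of(v2)
    var1, var2 = genotypes.variants[i1], genotypes.variants[i2]
    g1, g2 = genotypes.codes[:, i1], genotypes.codes[:, i2]
    complete = (g1 != MISSING) & (g2 != MISSING)
    labels = _joint_labels((var1.ref, var1.alt), (var2.ref, var2.alt))
    hap_labels = [
        f"{var1.ref}/{var2.ref}", f"{var1.ref}/{var2.alt}",
        f"{var1.alt}/{var2.ref}", f"{var1.alt}/{var2.alt}",
    ]

    freq_cols: dict[str, np.ndarray] = {}
    hap_cols: dict[str, np.ndarray] = {}
    counts_by_group: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    excluded: list[str] = []
    for name, mask in groups.items():
        use = np.asarray(mask, bool) & complete
        n = int(use.sum())
        if n == 0:
            warnings.warn(f"group {name!r}: no complete cases, excluded", stacklevel=2)
            excluded.append(name)
            continue
        joint = np.zeros(9, dtype=np.int64)
        for a, b in zip(g1[use], g2[use]):
            joint[3 * a + b] += 1
        counts_by_group[name] = joint
        freq_cols[name] = joint / n
        sizes[name] = n
        em = ldmod.em_from_table(joint.reshape(3, 3))
        hap_cols[name] = np.asarray(em.hap_freqs)

    comparisons = []
    for (na, nb) in itertools.combinations(counts_by_group, 2):
        ca, cb = counts_by_group[na], counts_by_group[nb]
        for k, lab in enumerate(labels):
            tab = np.array([
                [ca[k], ca.sum() - ca[k]],
                [cb[k], cb.sum() - cb[k]],
            ])
            expected = st.contingency.expected_freq(tab.astype(float))
            if (expected < expected_min).any():
                p, _ = fisher_exact(tab)
                test = "fisher"
            else:
                _, _, p = pearson_chi2(tab)
                test = "chi2"
            comparisons.append(
                {"group_a": na, "group_b": nb, "genotype": lab, "p": p, "test": test}
            )

    return CumulativeGenotypeTable(
        variant_pair=(var1.id, var2.id),
        genotype_freqs=pd.DataFrame(freq_cols, index=labels),
        hap_freqs=pd.DataFrame(hap_cols, index=hap_labels),
        group_sizes=sizes,
        comparisons=pd.DataFrame(
            comparisons, columns=["group_a", "group_b", "genotype", "p", "test"]
        ),
        excluded_groups=excluded,
    )


# ---------------------------------------------------------------------------
# full suite
# ---------------------------------------------------------------------------

STRATA = ("all", "normal", "overweight", "obese", "nonobese", "non_normal")


def stratum_mask(samples: Sequence[SampleRecord], stratum: str) -> np.ndarray:
    """Boolean mask over samples for a named BMI stratum."""
    classes = np.array([s.bmi_class.value for s in samples])
    if stratum == "all":
        return np.ones(len(classes), dtype=bool)
    if stratum == "nonobese":
        return classes != BmiClass.obese.value
    if stratum == "non_normal":
        return classes != BmiClass.normal.value
    if stratum in (c.value for c in BmiClass):
        return classes == stratum
    raise ValueError(f"unknown stratum {stratum!r}")


def _iter_model_rows(case: GenotypeCounts, control: GenotypeCounts):
    for model in MODELS:
        if model == "codominant":
            for pair in CODOMINANT_PAIRS:
                yield model_table(case, control, model, pair)
        else:
            yield model_table(case, control, model)


def run_association_suite(
    genotypes: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    contrasts: Sequence[tuple[str, str, str]] | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run HWE + all genetic-model contrasts for every variant.

    ``contrasts`` is a list of (name, group_A spec, group_B spec); each spec
    is ``status:stratum`` with status in {case, control, any} and stratum in
    {all, normal, overweight, obese, nonobese, non_normal}.  Group A is the
    exposure-of-interest group (numerator of the OR); per contrast and model
    both crude and covariate-adjusted odds ratios are reported.

    Defaults reproduce the usual layout: case vs control overall and within
    BMI strata, plus obese vs overweight / nonobese comparisons ignoring
    status.
    """
    config = config or PipelineConfig()
    if contrasts is None:
        contrasts = [
            ("crc_vs_control", "case:all", "control:all"),
            ("crc_vs_control_overweight", "case:overweight", "control:overweight"),
            ("crc_vs_control_nonobese", "case:nonobese", "control:nonobese"),
            ("obese_vs_overweight", "any:obese", "any:overweight"),
            ("obese_vs_nonobese", "any:obese", "any:nonobese"),
            ("obese_vs_overweight_cases", "case:obese", "case:overweight"),
        ]
    if [s.sample_id for s in samples] != genotypes.samples:
        raise ValueError("sample table and genotype matrix must list the same samples in order")

    status = np.array([s.status == Status.case for s in samples])
    cov_frame = pd.DataFrame(
        {name: [s.covariates.get(name, np.nan) for s in samples] for name in config.covariates}
    )

    hwe_rows = []
    assoc_rows = []
    skipped = []
    for j, variant in enumerate(genotypes.variants):
        col = genotypes.codes[:, j]

        for stratum in STRATA:
            mask = stratum_mask(samples, stratum) & ~status  # controls only
            if mask.sum() == 0:
                continue
            counts = genotype_counts(col[mask])
            if counts.total == 0:
                continue
            res = hwe_test(counts)
            hwe_rows.append(
                {"variant": variant.id, "stratum": stratum, "n": counts.total,
                 "chi2": res.chi2, "p": res.p, "defined": res.defined, "note": res.note}
            )

        for cname, spec_a, spec_b in contrasts:
            mask_a = _group_mask(samples, status, spec_a)
            mask_b = _group_mask(samples, status, spec_b)
            if mask_a.sum() < config.min_stratum_size or mask_b.sum() < config.min_stratum_size:
                skipped.append((variant.id, cname, "stratum below minimum size"))
                continue
            ca = genotype_counts(col[mask_a])
            cb = genotype_counts(col[mask_b])
            if ca.monomorphic and cb.monomorphic:
                assoc_rows.append(
                    {"variant": variant.id, "contrast": cname, "model": "all",
                     "or_crude": np.nan, "p_crude": np.nan, "or_adj": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "p_adj": np.nan,
                     "n": ca.total + cb.total, "note": "monomorphic: not analyzable"}
                )
                continue
            for tab in _iter_model_rows(ca, cb):
                crude = crude_or(tab, config.ci_level)
                adj = _adjusted_for_contrast(
                    col, mask_a, mask_b, tab.model, tab.label, cov_frame, config
                )
                assoc_rows.append(
                    {"variant": variant.id, "contrast": cname, "model": tab.label,
                     "or_crude": crude.or_point, "p_crude": crude.p,
                     "or_adj": adj.or_point, "ci_low": adj.ci_low,
                     "ci_high": adj.ci_high, "p_adj": adj.p,
                     "n": crude.n_used, "note": adj.note or crude.note}
                )

    return {
        "hwe": pd.DataFrame(hwe_rows),
        "association": pd.DataFrame(assoc_rows),
        "skipped": pd.DataFrame(skipped, columns=["variant", "contrast", "reason"]),
    }


def _group_mask(samples: Sequence[SampleRecord], status: np.ndarray, spec: str) -> np.ndarray:
    st_part, stratum = spec.split(":")
    mask = stratum_mask(samples, stratum)
    if st_part == "case":
        mask = mask & status
    elif st_part == "control":
        mask = mask & ~status
    elif st_part != "any":
        raise ValueError(f"unknown status selector {st_part!r} in {spec!r}")
    return mask


_EXPOSURE_CODE = {
    "dominant": lambda g: (g >= 1).astype(float),
    "recessive": lambda g: (g == 2).astype(float),
    "overdominant": lambda g: (g == 1).astype(float),
    "allelic": lambda g: g / 2.0,  # per-allele dosage
}


def _adjusted_for_contrast(col, mask_a, mask_b, model, label,
                           cov_frame, config) -> AssociationResult:
    """Adjusted OR for group A membership vs genotype exposure, complete cases."""
    sel = (mask_a | mask_b) & (col != MISSING)
    if model == "codominant":
        # label is 'codominant:<exp>_vs_<ref>'
        exp_name, ref_name = label.split(":")[1].split("_vs_")
        code_of = {"ref_hom": 0, "het": 1, "alt_hom": 2}
        keep = np.isin(col, [code_of[exp_name], code_of[ref_name]]) & sel
        exposure = (col == code_of[exp_name]).astype(float)
        sel = keep
    else:
        exposure = _EXPOSURE_CODE[model](col.astype(float))
    outcome = mask_a.astype(float)
    cov = cov_frame.loc[sel].reset_index(drop=True)
    cov = cov.dropna(axis=1, how="any")
    y = outcome[sel]
    x = exposure[sel]
    if y.min() == y.max() or x.min() == x.max():
        return AssociationResult(
            model=label, or_point=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), p=float("nan"), adjusted=True,
            covariates=list(cov.columns), n_used=int(sel.sum()),
            defined=False, note="degenerate contrast",
        )
    try:
        return adjusted_or(y, x, cov, config.ci_level, model=label)
    except ValueError as exc:
        return AssociationResult(
            model=label, or_point=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), p=float("nan"), adjusted=True,
            covariates=list(cov.columns), n_used=int(sel.sum()),
            defined=False, note=str(exc),
        )
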