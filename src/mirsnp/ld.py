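"""Linkage-disequilibrium statistics and two-locus EM haplotype estimation.

Conventions: allele 1 is the alternate allele at each locus; ``p1``/``p2``
below are alternate-allele frequencies.  Haplotype order throughout is
(AB, Ab, aB, ab) where A/B denote the *reference* alleles of locus 1/2, so
``hap_freqs[3]`` is the alt-alt haplotype.

D is computed on the alt-alt haplotype: D = f(alt,alt) - p1*p2.  D' scales D
to its frequency-determined bound; r^2 is the squared allele correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import MISSING, GenotypeMatrix, HaplotypePanel, PipelineConfig

__all__ = [
    "LDStats",
    "EMResult",
    "ld_from_freqs",
    "ld_from_phased",
    "em_two_locus",
    "ld_from_unphased",
    "proxy_expand",
]


@dataclass
class LDStats:
    d: float
    d_prime: float
    r2: float
    hap_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab); a/b = alt
    allele_freqs: tuple[float, float]  # alt-allele frequencies (p1, p2)
    n_chromosomes: int
    defined: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.defined:
            assert abs(sum(self.hap_freqs) - 1.0) < 1e-9
            assert -1e-9 <= self.r2 <= 1.0 + 1e-9
            assert abs(self.d_prime) <= 1.0 + 1e-9


def _undefined_ld(n: int, note: str) -> LDStats:
    return LDStats(
        d=0.0, d_prime=0.0, r2=0.0,
        hap_freqs=(0.0, 0.0, 0.0, 0.0), allele_freqs=(0.0, 0.0),
        n_chromosomes=n, defined=False, note=note,
    )


def ld_from_freqs(freqs: tuple[float, float, float, float],
                  n_chromosomes: int = 0) -> LDStats:
    """LD statistics from four haplotype frequencies or counts (AB, Ab, aB, ab).

    Shared kernel behind :func:`ld_from_phased` / :func:`ld_from_unphased`;
    unnormalized counts are accepted and normalized.
    """
    f_AB, f_Ab, f_aB, f_ab = freqs
    total = f_AB + f_Ab + f_aB + f_ab
    if total <= 0:
        return _undefined_ld(n_chromosomes, "no haplotypes")
    f_AB, f_Ab, f_aB, f_ab = (f / total for f in freqs)
    p1 = f_aB + f_ab  # alt frequency at locus 1
    p2 = f_Ab + f_ab  # alt frequency at locus 2
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return _undefined_ld(n_chromosomes, "monomorphic locus")
    d = f_ab - p1 * p2
    if d > 0:
        d_max = min(p1 * (1 - p2), (1 - p1) * p2)
    else:
        d_max = min(p1 * p2, (1 - p1) * (1 - p2))
    d_prime = d / d_max if d_max > 0 else 0.0
    r2 = d * d / (p1 * (1 - p1) * p2 * (1 - p2))
    return LDStats(
        d=d, d_prime=d_prime, r2=min(r2, 1.0),
        hap_freqs=(f_AB, f_Ab, f_aB, f_ab),
        allele_freqs=(p1, p2), n_chromosomes=n_chromosomes,
    )


def ld_from_phased(panel: HaplotypePanel, v1: int | str, v2: int | str) -> LDStats:
    """Pairwise D, D' and r^2 by direct gamete counting on a phased panel."""
    i = v1 if isinstance(v1, int) else panel.index_of(v1)
    j = v2 if isinstance(v2, int) else panel.index_of(v2)
    a, b = panel.alleles[i], panel.alleles[j]
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    f_ab = float(np.mean((a == 1) & (b == 1)))
    f_aB = float(np.mean((a == 1) & (b == 0)))
    f_Ab = float(np.mean((a == 0) & (b == 1)))
    f_AB = float(np.mean((a == 0) & (b == 0)))
    return ld_from_freqs((f_AB, f_Ab, f_aB, f_ab), n_chromosomes=n)


@dataclass
class EMResult:
    hap_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab)
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_samples: int
    ll_trace: list[float] = field(default_factory=list)
    note: str = ""


def _joint_genotype_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table of complete-case joint genotype counts."""
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[keep], g2[keep]
    table = np.zeros((3, 3), dtype=np.int64)
    for x, y in zip(g1, g2):
        table[x, y] += 1
    return table


def em_from_table(table: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> EMResult:
    """Two-locus EM on a 3x3 joint genotype table.

    Genotype code k at a locus contributes k alt alleles.  The only phase
    ambiguity is the double heterozygote (1,1), which is split between
    AB/ab and Ab/aB resolutions in proportion to the current products
    f(AB)*f(ab) and f(Ab)*f(aB).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n <= 0:
        raise ValueError("no informative samples for EM")

    # fixed haplotype contributions of each unambiguous cell; order (AB, Ab, aB, ab)
    # cell (i, j): i alt alleles at locus 1, j at locus 2
    fixed = np.zeros(4)
    contrib = {  # (i, j) -> counts of (AB, Ab, aB, ab) per individual
        (0, 0): (2, 0, 0, 0), (0, 1): (1, 1, 0, 0), (0, 2): (0, 2, 0, 0),
        (1, 0): (1, 0, 1, 0), (1, 2): (0, 1, 0, 1),
        (2, 0): (0, 0, 2, 0), (2, 1): (0, 0, 1, 1), (2, 2): (0, 0, 0, 2),
    }
    for (i, j), c in contrib.items():
        fixed += table[i, j] * np.asarray(c, dtype=float)
    n_dh = table[1, 1]  # double heterozygotes: AB+ab or Ab+aB

    # initialize at linkage equilibrium from marginal allele frequencies
    alt1 = (table[1, :].sum() + 2 * table[2, :].sum() ) / (2 * n)
    alt2 = (table[:, 1].sum() + 2 * table[:, 2].sum()) / (2 * n)
    p = np.array([
        (1 - alt1) * (1 - alt2), (1 - alt1) * alt2,
        alt1 * (1 - alt2), alt1 * alt2,
    ])
    p = np.clip(p, 1e-12, None)
    p /= p.sum()

    ll_trace: list[float] = []
    converged = False
    note = ""
    it = 0
    for it in range(1, max_iter + 1):
        cis = p[0] * p[3]  # AB/ab resolution weight
        trans = p[1] * p[2]  # Ab/aB resolution weight
        denom = cis + trans
        if denom <= 0:
            w = 0.5
        else:
            w = cis / denom
        counts = fixed.copy()
        counts[0] += n_dh * w
        counts[3] += n_dh * w
        counts[1] += n_dh * (1 - w)
        counts[2] += n_dh * (1 - w)
        new_p = counts / counts.sum()
        ll = _table_loglik(table, new_p)
        ll_trace.append(ll)
        delta = float(np.max(np.abs(new_p - p)))
        p = new_p
        if delta < tol:
            converged = True
            break
    if n_dh > 0 and abs(p[0] * p[3] - p[1] * p[2]) < 1e-12:
        note = "symmetric likelihood: double-het phase split left at fixed point"
    return EMResult(
        hap_freqs=tuple(p), log_likelihood=ll_trace[-1],
        n_iterations=it, converged=converged, n_samples=int(n),
        ll_trace=ll_trace, note=note,
    )


def _table_loglik(table: np.ndarray, p: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table given hap freqs."""
    f_AB, f_Ab, f_aB, f_ab = p
    probs = np.empty((3, 3))
    probs[0, 0] = f_AB ** 2
    probs[0, 1] = 2 * f_AB * f_Ab
    probs[0, 2] = f_Ab ** 2
    probs[1, 0] = 2 * f_AB * f_aB
    probs[1, 1] = 2 * f_AB * f_ab + 2 * f_Ab * f_aB
    probs[1, 2] = 2 * f_Ab * f_ab
    probs[2, 0] = f_aB ** 2
    probs[2, 1] = 2 * f_aB * f_ab
    probs[2, 2] = f_ab ** 2
    mask = table > 0
    return float(np.sum(table[mask] * np.log(np.clip(probs[mask], 1e-300, None))))


def em_two_locus(genotypes: GenotypeMatrix, v1: int | str, v2: int | str,
                 tol: float = 1e-10, max_iter: int = 1000) -> EMResult:
    """EM haplotype-frequency estimation for two loci from unphased genotypes."""
    g1 = genotypes.column(v1)
    g2 = genotypes.column(v2)
    table = _joint_genotype_counts(g1, g2)
    return em_from_table(table, tol=tol, max_iter=max_iter)


def ld_from_unphased(genotypes: GenotypeMatrix, v1: int | str, v2: int | str,
                     tol: float = 1e-10, max_iter: int = 1000) -> LDStats:
    """LD statistics from unphased genotypes via EM haplotype frequencies."""
    em = em_two_locus(genotypes, v1, v2, tol=tol, max_iter=max_iter)
    return ld_from_freqs(em.hap_freqs, n_chromosomes=2 * em.n_samples)


def proxy_expand(
    index_variants: list[str],
    panel: HaplotypePanel,
    config: PipelineConfig | None = None,
) -> tuple[dict[str, set[tuple[str, float]]], list[str]]:
    """Expand GWAS index variants to LD proxies on a phased panel.

    Returns ``(proxies, skipped)`` where ``proxies`` maps each found index
    rsID to the set of ``(proxy rsID, r2)`` with r2 >= threshold (inclusive)
    within the search window; the index itself is included with r2 = 1.
    Indices absent from the panel land in ``skipped``.
    """
    config = config or PipelineConfig()
    result: dict[str, set[tuple[str, float]]] = {}
    skipped: list[str] = []
    id_to_idx = {v.id: i for i, v in enumerate(panel.variants)}
    for rsid in index_variants:
        if rsid not in id_to_idx:
            skipped.append(rsid)
            continue
        i = id_to_idx[rsid]
        vi = panel.variants[i]
        proxies: set[tuple[str, float]] = {(rsid, 1.0)}
        for j, vj in enumerate(panel.variants):
            if j == i or vj.chrom != vi.chrom:
                continue
            if abs(vj.pos - vi.pos) > config.proxy_window_bp:
                continue
            stats = ld_from_phased(panel, i, j)
            if stats.defined and stats.r2 >= config.r2_threshold:
                proxies.add((vj.id, stats.r2))
        result[rsid] = proxies
    return result, skipped
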