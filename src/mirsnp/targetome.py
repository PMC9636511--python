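"""Intersection of candidate variants with miRNA binding sites and flanks.

A variant "hits" a site when its position falls in the site interval
extended by ``flank_nt`` on each side.  Placement distinguishes the site
proper (``in_site``) from the flanking region (``flank``); the flank
boundary is inclusive, so a variant exactly ``flank_nt`` bp away counts.
Strand is carried through for reporting but does not affect intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .io_model import (
    BindingSite,
    PathwaySet,
    PipelineConfig,
    Placement,
    VariantRecord,
)

__all__ = [
    "Interaction",
    "extend_site",
    "intersect_variants",
    "filter_by_pathways",
    "summarize_interactions",
    "interactions_to_frame",
]


@dataclass
class Interaction:
    """A (miRNA, gene, variant) triple with the variant's placement.

    ``distance_to_site`` is 0 inside the site, negative upstream of
    ``site.start`` and positive at/after ``site.end``.
    """

    mirna: str
    gene: str
    variant: VariantRecord
    placement: Placement
    site: BindingSite
    distance_to_site: int
    pathways: list[tuple[str, str]] = field(default_factory=list)  # (name, source)


def extend_site(site: BindingSite, flank_nt: int) -> tuple[int, int]:
    """Half-open interval covering the site plus ``flank_nt`` on each side.

    Returns [start - flank_nt, end + flank_nt), clamped at 0 on the left.
    In half-open coordinates this is symmetric: a variant exactly flank_nt
    bp before the first site base is included, as is one flank_nt - 1 bp
    past the last site base (the last position of [end, end + flank_nt)).
    """
    if flank_nt < 0:
        raise ValueError("flank_nt must be >= 0")
    return max(0, site.start - flank_nt), site.end + flank_nt


def _classify(pos: int, site: BindingSite, flank_nt: int) -> tuple[Placement, int] | None:
    if site.start <= pos < site.end:
        return Placement.in_site, 0
    if site.start - flank_nt <= pos < site.start:
        return Placement.flank, pos - site.start
    if site.end <= pos < site.end + flank_nt:
        return Placement.flank, pos - site.end + 1
    return None


def intersect_variants(
    variants: list[VariantRecord],
    sites: list[BindingSite],
    config: PipelineConfig | None = None,
) -> list[Interaction]:
    """All (variant, site) pairs where the variant lies in the extended site.

    Deterministic: output sorted by (chrom, pos, gene, mirna, site start).
    Overlapping sites each contribute their own interaction.
    """
    config = config or PipelineConfig()
    flank = config.flank_nt
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        lo, hi = extend_site(s, flank)
        trees.setdefault(s.chrom, IntervalTree()).addi(lo, hi, s)
    out: list[Interaction] = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for iv in tree.at(v.pos):
            s: BindingSite = iv.data
            hit = _classify(v.pos, s, flank)
            if hit is None:
                continue
            placement, dist = hit
            out.append(Interaction(s.mirna, s.gene, v, placement, s, dist))
    out.sort(key=lambda x: (x.variant.chrom, x.variant.pos, x.gene, x.mirna,
                            x.site.start, x.site.end))
    return out


def filter_by_pathways(
    interactions: list[Interaction],
    pathways: list[PathwaySet],
    inflammatory_only: bool = True,
) -> list[Interaction]:
    """Keep interactions whose gene is in at least one (inflammatory) pathway.

    Kept interactions are annotated with their pathway (name, source) pairs;
    a gene in several pathways yields one interaction with several
    annotations, never duplicates.
    """
    if not pathways:
        warnings.warn("empty pathway list: all interactions filtered out", stacklevel=2)
        return []
    gene_to_pathways: dict[str, list[tuple[str, str]]] = {}
    for p in pathways:
        if inflammatory_only and not p.inflammatory:
            continue
        for g in p.genes:
            gene_to_pathways.setdefault(g, []).append((p.name, p.source))
    kept = []
    for ix in interactions:
        ann = gene_to_pathways.get(ix.gene)
        if ann:
            ix.pathways = sorted(ann)
            kept.append(ix)
    return kept


def summarize_interactions(interactions: list[Interaction]) -> pd.DataFrame:
    """Per-gene counts of in-site and flank interactions."""
    if not interactions:
        return pd.DataFrame(columns=["gene", "in_site", "flank"]).set_index("gene")
    rows = [{"gene": ix.gene, "placement": ix.placement.value} for ix in interactions]
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["gene", "placement"]).size().unstack(fill_value=0)
        .reindex(columns=["in_site", "flank"], fill_value=0)
    )
    table.columns.name = None
    return table


def interactions_to_frame(interactions: list[Interaction]) -> pd.DataFrame:
    """Flat table of interactions for TSV report output."""
    rows = []
    for ix in interactions:
        rows.append(
            {
                "mirna": ix.mirna,
                "gene": ix.gene,
                "variant_id": ix.variant.id,
                "chrom": ix.variant.chrom,
                "pos": ix.variant.pos,
                "placement": ix.placement.value,
                "distance_to_site": ix.distance_to_site,
                "site_start": ix.site.start,
                "site_end": ix.site.end,
                "strand": ix.site.strand,
                "source": ix.site.source,
                "pathways": ";".join(f"{n}({s})" for n, s in ix.pathways),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "gene", "variant_id", "chrom", "pos", "placement",
            "distance_to_site", "site_start", "site_end", "strand", "source",
            "pathways",
        ],
    )
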