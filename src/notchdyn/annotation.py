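"""Positioning binding sites relative to gene models.

Covers distance to the nearest TSS, a single positional category per site
(promoter / UTRs / gene body / downstream / intergenic, with intron and
exon collapsed into "gene body"), regulatory-domain gene association in the
basal-plus-extension style (basal promoter domain 5 kb upstream / 1 kb
downstream of the TSS, extended up to 1 Mb but never into a neighbouring
gene's basal domain), and plain interval overlap summaries (e.g. against
CpG islands). The site midpoint drives categorization and association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genomic_io import GeneModel, GenomicInterval, merge_intervals, overlaps_any

CATEGORIES = (
    "promoter",
    "five_prime_utr",
    "three_prime_utr",
    "gene_body",
    "downstream",
    "intergenic",
)

BASAL_UP = 5_000
BASAL_DOWN = 1_000
MAX_EXTENSION = 1_000_000
PROMOTER_WINDOW = (3_000, 3_000)
DOWNSTREAM_WINDOW = 3_000


@dataclass
class SiteAnnotation:
    site_id: str
    category: str
    nearest_gene: str
    tss_distance: int  # signed; negative = upstream of the gene


def distance_to_tss(
    site: GenomicInterval, genes: list[GeneModel]
) -> tuple[str | None, int | None]:
    """Nearest TSS by absolute distance; sign follows gene orientation.

    distance = midpoint - TSS for + genes, TSS - midpoint for - genes, so
    negative always means upstream of the gene. Ties break to the
    lexicographically smaller gene_id. Returns (None, None) when the
    chromosome has no gene.
    """
    mid = site.midpoint
    best: tuple[int, str, int] | None = None
    for g in genes:
        if g.interval.chrom != site.chrom:
            continue
        signed = mid - g.tss if g.strand == "+" else g.tss - mid
        key = (abs(signed), g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(signed), g.gene_id, signed)
    if best is None:
        return None, None
    return best[1], best[2]


def _midpoint_in(mid: int, iv: GenomicInterval) -> bool:
    return iv.start <= mid < iv.end


def categorize(
    site: GenomicInterval,
    genes: list[GeneModel],
    site_id: str = "",
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    downstream_window: int = DOWNSTREAM_WINDOW,
) -> SiteAnnotation:
    """Assign exactly one positional category to the site midpoint.

    Precedence: promoter > 5'UTR > 3'UTR > gene body > downstream >
    intergenic, evaluated over all genes on the chromosome.
    """
    mid = site.midpoint
    nearest_gene, tss_dist = distance_to_tss(site, genes)
    chrom_genes = [g for g in genes if g.interval.chrom == site.chrom]

    up, down = promoter_window
    in_promoter = in_utr5 = in_utr3 = in_body = in_downstream = False
    for g in chrom_genes:
        if g.strand == "+":
            promoter = (g.tss - up, g.tss + down + 1)
            downstream = (g.interval.end, g.interval.end + downstream_window)
        else:
            promoter = (g.tss - down, g.tss + up + 1)
            downstream = (g.interval.start - downstream_window, g.interval.start)
        if promoter[0] <= mid < promoter[1]:
            in_promoter = True
        if any(_midpoint_in(mid, u) for u in g.utr5):
            in_utr5 = True
        if any(_midpoint_in(mid, u) for u in g.utr3):
            in_utr3 = True
        if _midpoint_in(mid, g.interval):
            in_body = True
        if downstream[0] <= mid < downstream[1]:
            in_downstream = True

    if in_promoter:
        category = "promoter"
    elif in_utr5:
        category = "five_prime_utr"
    elif in_utr3:
        category = "three_prime_utr"
    elif in_body:
        category = "gene_body"
    elif in_downstream:
        category = "downstream"
    else:
        category = "intergenic"
    return SiteAnnotation(
        site_id=site_id,
        category=category,
        nearest_gene=nearest_gene if nearest_gene is not None else "",
        tss_distance=tss_dist if tss_dist is not None else 0,
    )


def annotate_sites(
    sites: list[GenomicInterval],
    genes: list[GeneModel],
    site_ids: list[str] | None = None,
    **kwargs,
) -> list[SiteAnnotation]:
    if site_ids is None:
        site_ids = [f"site_{i:05d}" for i in range(len(sites))]
    return [
        categorize(site, genes, site_id=sid, **kwargs)
        for sid, site in zip(site_ids, sites)
    ]


def regulatory_domains(
    genes: list[GeneModel],
    basal_up: int = BASAL_UP,
    basal_down: int = BASAL_DOWN,
    max_extension: int = MAX_EXTENSION,
) -> dict[str, tuple[int, int]]:
    """Materialize each gene's basal-plus-extension regulatory domain.

    The basal domain runs ``basal_up`` upstream to ``basal_down`` downstream
    of the TSS in strand orientation. Each edge then extends outward up to
    ``max_extension`` bp, stopping at the nearest neighbouring basal domain
    (domains may overlap basal domains already overlapping the basal span).
    """
    basal: dict[str, tuple[str, int, int]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.strand == "+":
            b = (g.tss - basal_up, g.tss + basal_down)
        else:
            b = (g.tss - basal_down + 1, g.tss + basal_up + 1)
        b = (max(b[0], 0), b[1])
        basal[g.gene_id] = (g.interval.chrom, b[0], b[1])
        by_chrom.setdefault(g.interval.chrom, []).append(b)

    # per chromosome: prefix max of basal ends ordered by start (for the
    # left clip) and suffix min of basal starts ordered by end (right clip)
    indexed: dict[str, dict] = {}
    for chrom, spans in by_chrom.items():
        arr = np.asarray(spans, dtype=np.int64)
        by_start = arr[np.argsort(arr[:, 0], kind="stable")]
        by_end = arr[np.argsort(arr[:, 1], kind="stable")]
        indexed[chrom] = {
            "starts": by_start[:, 0],
            "prefix_max_end": np.maximum.accumulate(by_start[:, 1]),
            "ends": by_end[:, 1],
            "suffix_min_start": np.minimum.accumulate(by_end[:, 0][::-1])[::-1],
        }

    domains: dict[str, tuple[int, int]] = {}
    for gid, (chrom, b_start, b_end) in basal.items():
        idx = indexed[chrom]
        left = b_start - max_extension
        right = b_end + max_extension
        # nearest neighbouring basal edge clips the extension; a neighbour
        # whose basal span overlaps this one suppresses extension entirely
        # on that side (extension never enters a basal domain, but the
        # gene's own basal span is always kept)
        i = int(np.searchsorted(idx["starts"], b_start, side="left")) - 1
        if i >= 0:
            left = max(left, min(int(idx["prefix_max_end"][i]), b_start))
        j = int(np.searchsorted(idx["ends"], b_end, side="right"))
        if j < len(idx["ends"]):
            right = min(right, max(int(idx["suffix_min_start"][j]), b_end))
        domains[gid] = (max(left, 0), right)
    return domains


@dataclass
class GeneAssociation:
    site_id: str
    gene_ids: frozenset[str]


def associate_genes(
    sites: list[GenomicInterval],
    genes: list[GeneModel],
    site_ids: list[str] | None = None,
    basal_up: int = BASAL_UP,
    basal_down: int = BASAL_DOWN,
    max_extension: int = MAX_EXTENSION,
) -> list[GeneAssociation]:
    """Associate each site with every gene whose domain holds its midpoint."""
    if site_ids is None:
        site_ids = [f"site_{i:05d}" for i in range(len(sites))]
    domains = regulatory_domains(genes, basal_up, basal_down, max_extension)
    chrom_of = {g.gene_id: g.interval.chrom for g in genes}
    out: list[GeneAssociation] = []
    for sid, site in zip(site_ids, sites):
        mid = site.midpoint
        hit = frozenset(
            gid
            for gid, (d_start, d_end) in domains.items()
            if chrom_of[gid] == site.chrom and d_start <= mid < d_end
        )
        out.append(GeneAssociation(site_id=sid, gene_ids=hit))
    return out


def overlap_fraction(
    sites_a: list[GenomicInterval], sites_b: list[GenomicInterval]
) -> tuple[int, float]:
    """(count, fraction) of a-sites sharing >=1 base with any b-interval."""
    if not sites_a:
        warnings.warn("empty site list; overlap fraction undefined")
        return 0, float("nan")
    merged = merge_intervals(sites_b)
    count = sum(1 for iv in sites_a if overlaps_any(iv, merged))
    return count, count / len(sites_a)
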