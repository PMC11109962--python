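"""Linking site classes to transcriptional response.

Deregulated genes are called at |log2FC| > 1 with adjusted p < 0.05 (strict
inequalities). Genes associated with at least one dynamic site are classed
dynamic (even when they also carry static sites), genes with only static
sites are static, and the rest are unassociated. Hypergeometric upper-tail
tests then ask whether deregulated genes concentrate in a gene class, with
a median split of sites by binding strength as the control comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .annotation import GeneAssociation
from .consensus import ConsensusSite
from .dynamics import BindingDynamics

DE_LOG2FC = 1.0
DE_PADJ = 0.05


@dataclass
class ExpressionRecord:
    gene_id: str
    log2fc: float
    padj: float
    status: str  # "up" | "down" | "ns"


@dataclass
class EnrichmentResult:
    group_name: str
    n_group: int
    n_overlap: int
    expected: float
    fold_enrichment: float
    p_value: float


def classify_deregulated(
    table: pd.DataFrame,
    log2fc_cutoff: float = DE_LOG2FC,
    padj_cutoff: float = DE_PADJ,
) -> list[ExpressionRecord]:
    """Call up/down/ns per gene from a (gene_id, log2fc, padj) table.

    Strict thresholds: up iff log2fc > cutoff and padj < padj_cutoff; down
    iff log2fc < -cutoff and padj < padj_cutoff. Missing padj means ns.
    """
    records: list[ExpressionRecord] = []
    for gene_id, row in table.iterrows():
        log2fc, padj = float(row["log2fc"]), float(row["padj"])
        if pd.isna(padj) or not padj < padj_cutoff:
            status = "ns"
        elif log2fc > log2fc_cutoff:
            status = "up"
        elif log2fc < -log2fc_cutoff:
            status = "down"
        else:
            status = "ns"
        records.append(ExpressionRecord(str(gene_id), log2fc, padj, status))
    return records


def assign_gene_class(
    associations: list[GeneAssociation],
    site_labels: list[BindingDynamics],
) -> dict[str, str]:
    """Per-gene class: dynamic beats static; unassociated genes excluded.

    Returns gene_id -> {"dynamic", "static"} for genes carrying >=1
    associated site; callers treat absent genes as unassociated.
    """
    label_by_site = {d.site_id: d.label for d in site_labels}
    gene_class: dict[str, str] = {}
    for assoc in associations:
        if assoc.site_id not in label_by_site:
            raise ValueError(f"no label for associated site {assoc.site_id}")
        label = label_by_site[assoc.site_id]
        for gid in assoc.gene_ids:
            if label == "dynamic":
                gene_class[gid] = "dynamic"
            else:
                gene_class.setdefault(gid, "static")
    return gene_class


def hypergeom_enrichment(
    group_genes: set[str],
    deregulated: set[str],
    universe: set[str],
    group_name: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of deregulated genes in a group.

    With N = |universe|, K = |universe ∩ deregulated|, n = |group| and
    k = |group ∩ deregulated|: p = P(X >= k), fold = (k/n) / (K/N).
    """
    if not group_genes <= universe:
        raise ValueError("group is not a subset of the universe")
    if len(universe) == 0:
        raise ValueError("empty universe")
    N = len(universe)
    K = len(deregulated & universe)
    n = len(group_genes)
    k = len(group_genes & deregulated)
    expected = n * K / N
    fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
    # P(X >= k) = sf(k - 1)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n > 0 else 1.0
    return EnrichmentResult(
        group_name=group_name,
        n_group=n,
        n_overlap=k,
        expected=expected,
        fold_enrichment=fold,
        p_value=min(max(p, 0.0), 1.0) or 1e-300,
    )


def median_split(sites: list[ConsensusSite]) -> tuple[set[str], set[str]]:
    """Split site ids by norm_score around the median (ties to bottom).

    The top half is strictly above the median; everything else, including
    sites exactly at the median, goes to the bottom half.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites for a median split")
    scores = pd.Series({s.site_id: s.norm_score for s in sites})
    median = float(scores.median())
    top = set(scores.index[scores > median])
    bottom = set(scores.index) - top
    if not top:
        warnings.warn("all scores at or below the median; top half is empty")
    return top, bottom


def enrichment_by_class(
    gene_class: dict[str, str],
    expression: list[ExpressionRecord],
    directions: tuple[str, ...] = ("up", "down"),
) -> list[EnrichmentResult]:
    """Enrichment of deregulated genes in the dynamic and static classes.

    The universe is every gene present in the expression table; deregulated
    pools the requested directions.
    """
    universe = {r.gene_id for r in expression}
    dereg = {r.gene_id for r in expression if r.status in directions}
    results = []
    for cls in ("dynamic", "static"):
        group = {g for g, c in gene_class.items() if c == cls} & universe
        results.append(
            hypergeom_enrichment(group, dereg, universe, group_name=cls)
        )
    return results
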