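"""End-to-end orchestration over a synthetic bundle.

Runs the whole chain — replicate consensus, occupancy classification, motif
flags, positional annotation, feature assembly, forest training/selection,
prediction, and target-gene enrichment — and scores each stage against the
planted truth. This is the path the acceptance checks and the worked
example in the README exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import annotate_sites, associate_genes
from .consensus import ConsensusSite, attach_norm_scores, build_consensus
from .dynamics import BindingDynamics, CountMatrix, classify_sites, count_in_windows
from .enrichment import (
    EnrichmentResult,
    assign_gene_class,
    classify_deregulated,
    enrichment_by_class,
)
from .genomic_io import merge_intervals
from .model import (
    SplitSpec,
    TrainedForest,
    build_feature_table,
    evaluate_forest,
    predict,
    split_data,
    train_and_select,
)
from .motifs import flag_sites
from .simulate import SyntheticBundle, truth_compare

MIN_SUPPORT = 3


@dataclass
class PipelineResult:
    consensus: list[ConsensusSite]
    matched_truth: pd.Series  # consensus site_id -> true site_id
    dynamics: list[BindingDynamics]
    feature_table: pd.DataFrame
    model: TrainedForest
    validation_metrics: dict[str, float]
    test_metrics: dict[str, float]
    classification_vs_truth: dict[str, float]
    enrichment: list[EnrichmentResult] = field(default_factory=list)


def match_consensus_to_truth(
    consensus: list[ConsensusSite], bundle: SyntheticBundle
) -> pd.Series:
    """Map consensus sites to the planted site each one overlaps.

    Consensus sites derived purely from background peaks have no match and
    are absent from the result.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for sid, iv in zip(bundle.site_ids, bundle.sites):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, sid))
    for spans in by_chrom.values():
        spans.sort()
    mapping: dict[str, str] = {}
    for site in consensus:
        spans = by_chrom.get(site.interval.chrom, [])
        starts = [s for s, _, _ in spans]
        idx = np.searchsorted(starts, site.interval.end) - 1
        if idx >= 0:
            s, e, sid = spans[idx]
            if e > site.interval.start:  # >=1 bp overlap
                mapping[site.site_id] = sid
    return pd.Series(mapping, dtype=object)


def counts_for_consensus(
    consensus: list[ConsensusSite],
    matched: pd.Series,
    bundle: SyntheticBundle,
    flank: int = 0,
) -> tuple[list[ConsensusSite], CountMatrix]:
    """Site x sample counts for matched consensus sites.

    When the bundle materialized read intervals the counts are recomputed
    from them over the consensus windows; otherwise the bundle's count
    table is carried over through the truth match. Unmatched (background)
    consensus sites are dropped.
    """
    kept = [s for s in consensus if s.site_id in matched.index]
    if bundle.reads is not None:
        cm = count_in_windows(
            [s.interval for s in kept],
            bundle.reads,
            bundle.counts.conditions.to_dict(),
            flank=flank,
            site_ids=[s.site_id for s in kept],
        )
        return kept, cm
    true_ids = [matched[s.site_id] for s in kept]
    counts = bundle.counts.counts.loc[true_ids].copy()
    counts.index = [s.site_id for s in kept]
    return kept, CountMatrix(counts=counts, conditions=bundle.counts.conditions)


def run_pipeline(
    bundle: SyntheticBundle,
    min_support: int = MIN_SUPPORT,
    model_seed: int = 0,
    n_candidates: int = 10,
    with_enrichment: bool = True,
) -> PipelineResult:
    """Run every stage on a synthetic bundle and score against truth."""
    consensus = build_consensus(bundle.replicate_peaks, min_support=min_support)
    attach_norm_scores(consensus)
    matched = match_consensus_to_truth(consensus, bundle)
    kept, cm = counts_for_consensus(consensus, matched, bundle)

    dynamics = classify_sites(cm, contrast="GSI_vs_control")
    label_by_id = pd.Series({d.site_id: d.label for d in dynamics})
    truth_labels = pd.Series(
        {
            s.site_id: bundle.site_truth.loc[matched[s.site_id], "label"]
            for s in kept
        }
    )
    classification_vs_truth = truth_compare(label_by_id, truth_labels)

    intervals = [s.interval for s in kept]
    ids = [s.site_id for s in kept]
    flags = flag_sites(intervals, bundle.genome, site_ids=ids)
    annotations = annotate_sites(intervals, bundle.genes, site_ids=ids)
    table = build_feature_table(kept, annotations, flags, labels=dynamics)

    train, validation, test = split_data(table, SplitSpec(seed=model_seed))
    model = train_and_select(
        train, validation, n_candidates=n_candidates, seed_base=model_seed
    )
    validation_metrics = evaluate_forest(model, validation)
    validation_metrics["mean_dynamic_tpr"] = model.validation_metrics.get(
        "mean_dynamic_tpr", validation_metrics["tpr_dynamic"]
    )
    test_metrics = evaluate_forest(model, test)

    enrichment: list[EnrichmentResult] = []
    if with_enrichment:
        associations = associate_genes(intervals, bundle.genes, site_ids=ids)
        gene_class = assign_gene_class(associations, dynamics)
        expression = classify_deregulated(bundle.expression)
        enrichment = enrichment_by_class(gene_class, expression)

    return PipelineResult(
        consensus=consensus,
        matched_truth=matched,
        dynamics=dynamics,
        feature_table=table,
        model=model,
        validation_metrics=validation_metrics,
        test_metrics=test_metrics,
        classification_vs_truth=classification_vs_truth,
        enrichment=enrichment,
    )
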