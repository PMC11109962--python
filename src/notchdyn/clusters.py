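"""Enhancer-cluster (super-enhancer style) stitching and ranking.

Acetylation peaks within a stitch distance (12.5 kb by default) are merged
into clusters, clusters are ranked by aggregate signal, and the top tier is
flagged at the rank-signal inflection: with both axes rescaled to [0, 1],
the cutoff sits where the vertical gap above the y = x diagonal is maximal
(the tangent-of-slope-1 rule). Dynamic RBPJ sites concentrate inside these
clusters far more than static ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import GenomicInterval, merge_intervals, overlaps_any

STITCH_DISTANCE = 12_500


@dataclass
class EnhancerCluster:
    interval: GenomicInterval
    constituent_count: int
    total_signal: float
    rank: int = -1
    is_top_tier: bool = False


def stitch(
    peaks: list[GenomicInterval],
    signals: list[float],
    stitch_distance: int = STITCH_DISTANCE,
) -> list[EnhancerCluster]:
    """Merge peaks whose gaps are <= stitch_distance (transitively).

    Cluster signal is the sum of constituent signals; the span is the union.
    """
    if stitch_distance < 0:
        raise ValueError("stitch distance must be >= 0")
    if len(peaks) != len(signals):
        raise ValueError("peaks and signals must align")
    if any(s < 0 for s in signals):
        raise ValueError("signals must be >= 0")
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for iv, sig in zip(peaks, signals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, sig))
    clusters: list[EnhancerCluster] = []
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom])
        cur_start, cur_end, cur_sig, cur_n = *rows[0][:2], rows[0][2], 1
        for start, end, sig in rows[1:]:
            if start - cur_end <= stitch_distance:
                cur_end = max(cur_end, end)
                cur_sig += sig
                cur_n += 1
            else:
                clusters.append(
                    EnhancerCluster(
                        GenomicInterval(chrom, cur_start, cur_end),
                        cur_n,
                        cur_sig,
                    )
                )
                cur_start, cur_end, cur_sig, cur_n = start, end, sig, 1
        clusters.append(
            EnhancerCluster(
                GenomicInterval(chrom, cur_start, cur_end), cur_n, cur_sig
            )
        )
    return clusters


def rank_and_cut(clusters: list[EnhancerCluster]) -> list[EnhancerCluster]:
    """Rank clusters by signal and flag the top tier at the inflection.

    Sorted ascending by signal with both axes scaled to [0, 1], the cutoff
    is the signal at the point of maximal vertical gap above the diagonal;
    clusters strictly above the cutoff signal are top tier. Fewer than 3
    clusters, or a flat curve, flags nothing.
    """
    order = np.argsort([c.total_signal for c in clusters], kind="stable")
    for rank_pos, idx in enumerate(order[::-1]):
        clusters[idx].rank = rank_pos + 1  # 1 = strongest
        clusters[idx].is_top_tier = False
    if len(clusters) < 3:
        return clusters
    signals = np.asarray([clusters[i].total_signal for i in order], dtype=float)
    lo, hi = signals[0], signals[-1]
    if hi == lo:
        return clusters
    y = (signals - lo) / (hi - lo)
    x = np.linspace(0.0, 1.0, len(signals))
    gap = y - x
    cut_idx = int(np.argmax(gap))
    cutoff = signals[cut_idx]
    for c in clusters:
        c.is_top_tier = c.total_signal > cutoff
    return clusters


def intersect_with_classes(
    clusters: list[EnhancerCluster],
    dynamic_sites: list[GenomicInterval],
    static_sites: list[GenomicInterval],
    genome_span: int,
) -> dict[str, dict[str, float]]:
    """Per-class overlap with clusters and fold over random expectation.

    fold = (fraction of class sites inside any cluster) / (total cluster
    span / effective genome span).
    """
    if genome_span <= 0:
        raise ValueError("genome span must be positive")
    if not dynamic_sites or not static_sites:
        raise ValueError("both site classes must be non-empty")
    merged = merge_intervals([c.interval for c in clusters])
    span = sum(int(np.sum(arr[:, 1] - arr[:, 0])) for arr in merged.values())
    expectation = span / genome_span
    out: dict[str, dict[str, float]] = {}
    for name, sites in (("dynamic", dynamic_sites), ("static", static_sites)):
        count = sum(1 for iv in sites if overlaps_any(iv, merged))
        fraction = count / len(sites)
        out[name] = {
            "count": float(count),
            "fraction": fraction,
            "fold": fraction / expectation if expectation > 0 else float("inf"),
        }
    return out
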