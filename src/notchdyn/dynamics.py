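"""Condition-dependent binding quantification and dynamic/static labels.

Occupancy at each consensus site is compared between Notch-on and Notch-off
conditions. A site is *dynamic* when its normalized occupancy drops by more
than 2^0.5-fold on GSI treatment (log2FC < -0.5) or rises correspondingly on
GSI washout (log2FC > 0.5); everything else is *static*. Normalization uses
median-of-ratios size factors; fold changes are unshrunk with a pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval

logger = logging.getLogger("notchdyn")

CONDITIONS = ("control", "GSI", "washout")
DYNAMIC_CUTOFF = 0.5


@dataclass
class CountMatrix:
    """Site x sample read counts plus per-sample condition metadata."""

    counts: pd.DataFrame  # index: site_id, columns: sample_id
    conditions: pd.Series  # index: sample_id -> condition

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition: {sorted(missing)}")
        bad = set(self.conditions.loc[list(self.counts.columns)]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    def samples_for(self, condition: str) -> list[str]:
        return [
            s for s in self.counts.columns if self.conditions[s] == condition
        ]


@dataclass
class BindingDynamics:
    site_id: str
    mean_control: float
    mean_treated: float
    log2fc: float
    label: str  # "dynamic" | "static"


def count_in_windows(
    sites: list[GenomicInterval],
    reads: dict[str, list[GenomicInterval]],
    conditions: dict[str, str],
    flank: int = 0,
    site_ids: list[str] | None = None,
) -> CountMatrix:
    """Count reads per sample overlapping each site extended by ``flank``.

    ``reads`` maps sample id -> read/fragment intervals. A read is counted
    when it shares >=1 base with the window [start-flank, end+flank) (window
    clipped at 0). Reads on chromosomes with no sites are ignored with a
    logged note.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if site_ids is None:
        site_ids = [f"site_{i:05d}" for i in range(len(sites))]
    site_chroms = {iv.chrom for iv in sites}

    mat = np.zeros((len(sites), len(reads)), dtype=np.int64)
    sample_ids = list(reads)
    for j, sample in enumerate(sample_ids):
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        extra = set()
        grouped: dict[str, list[tuple[int, int]]] = {}
        for iv in reads[sample]:
            if iv.chrom not in site_chroms:
                extra.add(iv.chrom)
                continue
            grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
        if extra:
            logger.info(
                "sample %s: ignoring reads on chromosomes without sites: %s",
                sample,
                sorted(extra),
            )
        for chrom, spans in grouped.items():
            arr = np.asarray(spans, dtype=np.int64)
            by_chrom[chrom] = (np.sort(arr[:, 0]), np.sort(arr[:, 1]))
        for i, site in enumerate(sites):
            entry = by_chrom.get(site.chrom)
            if entry is None:
                continue
            starts, ends = entry
            win_start = max(site.start - flank, 0)
            win_end = site.end + flank
            # overlap iff read.start < win_end and read.end > win_start
            n_start_ok = np.searchsorted(starts, win_end, side="left")
            n_end_bad = np.searchsorted(ends, win_start, side="right")
            mat[i, j] = n_start_ok - n_end_bad
    counts = pd.DataFrame(mat, index=site_ids, columns=sample_ids)
    cond = pd.Series({s: conditions[s] for s in sample_ids})
    return CountMatrix(counts=counts, conditions=cond)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization scheme).

    The reference for each site is the geometric mean of its counts across
    samples, computed over sites positive in every sample; each sample's
    factor is the median ratio of its counts to the reference.
    """
    mat = counts.values.astype(float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no site has positive counts in every sample; consider a "
            "pseudo-reference fallback"
        )
    sub = mat[all_positive]
    log_ref = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


_CONTRASTS = {
    "GSI_vs_control": ("control", "GSI", "lt"),
    "washout_vs_GSI": ("GSI", "washout", "gt"),
}


def classify_sites(
    cm: CountMatrix,
    contrast: str = "GSI_vs_control",
    cutoff: float = DYNAMIC_CUTOFF,
    pseudocount: float = 1.0,
) -> list[BindingDynamics]:
    """Label each site dynamic or static from its normalized fold change.

    log2FC = log2((mean normalized treated + pseudocount) /
    (mean normalized control + pseudocount)). Dynamic iff log2FC < -cutoff
    for the GSI contrast, or > +cutoff for the washout contrast (strict).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    ref_cond, alt_cond, direction = _CONTRASTS[contrast]
    ref_samples = cm.samples_for(ref_cond)
    alt_samples = cm.samples_for(alt_cond)
    if not ref_samples or not alt_samples:
        raise ValueError(
            f"contrast {contrast} needs samples in both {ref_cond!r} and "
            f"{alt_cond!r}"
        )
    factors = size_factors(cm.counts)
    norm = cm.counts / factors
    mean_ref = norm[ref_samples].mean(axis=1)
    mean_alt = norm[alt_samples].mean(axis=1)
    log2fc = np.log2((mean_alt + pseudocount) / (mean_ref + pseudocount))

    out: list[BindingDynamics] = []
    for site_id in cm.counts.index:
        fc = float(log2fc[site_id])
        if direction == "lt":
            dynamic = fc < -cutoff
        else:
            dynamic = fc > cutoff
        out.append(
            BindingDynamics(
                site_id=site_id,
                mean_control=float(mean_ref[site_id]),
                mean_treated=float(mean_alt[site_id]),
                log2fc=fc,
                label="dynamic" if dynamic else "static",
            )
        )
    return out


def dynamics_table(dynamics: list[BindingDynamics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [d.site_id for d in dynamics],
            "mean_control": [d.mean_control for d in dynamics],
            "mean_treated": [d.mean_treated for d in dynamics],
            "log2fc": [d.log2fc for d in dynamics],
            "label": [d.label for d in dynamics],
        }
    ).set_index("site_id")
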