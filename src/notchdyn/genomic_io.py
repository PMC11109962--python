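"""Genomic file formats and the internal coordinate convention.

Everything downstream works on 0-based half-open intervals. BED is native to
that convention; GTF (1-based, inclusive) is converted at the boundary and
converted back on write. p-values of exactly 0 are floored to ``P_FLOOR`` so
log transforms stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("notchdyn")

P_FLOOR = 1e-300

VALID_STRANDS = ("+", "-", ".")
DNA_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 shared base under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ReplicatePeak:
    """A single peak-caller call from one replicate."""

    interval: GenomicInterval
    p_value: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


@dataclass
class GeneModel:
    """A gene span with its TSS and (optionally) exon structure."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for exon in self.exons:
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(
                    f"exon [{exon.start},{exon.end}) outside gene span of "
                    f"{self.gene_id}"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path, dialect: str = "bed6") -> list[ReplicatePeak]:
    """Read peak calls from a BED6 or narrowPeak file.

    BED6: column 5 (score), when present and numeric, is taken as the raw
    p-value; absent scores default to 1.0. narrowPeak: column 8 carries
    -log10(p) per the ENCODE standard and is converted back to a p-value.
    Zero p-values are floored to ``P_FLOOR``. Input order is preserved.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    peaks: list[ReplicatePeak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"malformed line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"malformed line {lineno}: {exc}") from None
            if start >= end:
                raise ValueError(f"start >= end at line {lineno}")
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            if dialect == "narrowPeak":
                if len(fields) < 8:
                    raise ValueError(
                        f"malformed line {lineno}: narrowPeak needs >=8 columns"
                    )
                p_value = 10.0 ** -float(fields[7])
            else:
                p_value = 1.0
                if len(fields) > 4:
                    try:
                        p_value = float(fields[4])
                    except ValueError:
                        p_value = 1.0
            p_value = max(min(p_value, 1.0), P_FLOOR)
            peaks.append(
                ReplicatePeak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    p_value=p_value,
                )
            )
    return peaks


def write_bed(path, peaks: Sequence[ReplicatePeak]) -> None:
    """Write peaks as BED6 with the raw p-value in the score column."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            iv = pk.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t"
                f"{pk.p_value!r}\t{iv.strand}\n"
            )


def write_intervals_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tiv_{i}\t0\t{iv.strand}\n")


def read_intervals_bed(path) -> list[GenomicInterval]:
    """Read plain intervals (first three BED columns plus optional strand)."""
    return [p.interval for p in read_bed(path, dialect="bed6")]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) == 2:
            attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_gtf(path) -> list[GeneModel]:
    """Read gene models (``gene``/``exon``/UTR features) from a GTF file.

    GTF 1-based inclusive coordinates become 0-based half-open
    (start-1, end). The TSS is the interval start for + genes and end-1 for
    - genes. Genes are returned in file order.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line {lineno}")
            chrom, _, feature, start1, end1, _, strand, _, attr_text = fields[:9]
            if feature not in ("gene", "exon", "five_prime_utr", "three_prime_utr",
                              "5UTR", "3UTR"):
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"unknown strand {strand!r} at line {lineno}")
            attrs = _parse_gtf_attributes(attr_text)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"missing gene_id attribute at line {lineno}")
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            rec = genes.get(gene_id)
            if rec is None:
                rec = {"span": None, "strand": strand, "exons": [],
                       "utr5": [], "utr3": []}
                genes[gene_id] = rec
                order.append(gene_id)
            if feature == "gene":
                rec["span"] = iv
            elif feature == "exon":
                rec["exons"].append(iv)
            elif feature in ("five_prime_utr", "5UTR"):
                rec["utr5"].append(iv)
            else:
                rec["utr3"].append(iv)
    models: list[GeneModel] = []
    for gene_id in order:
        rec = genes[gene_id]
        span = rec["span"]
        if span is None:
            # gene line absent: infer the span from its parts
            parts = rec["exons"] + rec["utr5"] + rec["utr3"]
            if not parts:
                continue
            span = GenomicInterval(
                parts[0].chrom,
                min(p.start for p in parts),
                max(p.end for p in parts),
                rec["strand"],
            )
        models.append(
            GeneModel(
                gene_id=gene_id,
                interval=span,
                strand=rec["strand"],
                exons=rec["exons"],
                utr5=rec["utr5"],
                utr3=rec["utr3"],
            )
        )
    return models


def write_gtf(path, genes: Sequence[GeneModel], source: str = "notchdyn") -> None:
    """Write gene models back to GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            rows = [("gene", g.interval)]
            rows += [("exon", e) for e in g.exons]
            rows += [("five_prime_utr", u) for u in g.utr5]
            rows += [("three_prime_utr", u) for u in g.utr3]
            for feature, iv in rows:
                fh.write(
                    f"{iv.chrom}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}\t"
                    f".\t{g.strand}\t.\tgene_id \"{g.gene_id}\";\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a genome FASTA into a chrom -> uppercase sequence dict.

    Characters outside ACGTN are rejected: the motif scanner assumes a
    4-letter alphabet plus N.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {record.id} contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )
        genome[record.id] = seq
    return genome


def write_fasta(path, genome: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Interval set operations
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> dict[str, np.ndarray]:
    """Collapse intervals per chromosome into disjoint sorted spans.

    Returns chrom -> (k, 2) int array of merged [start, end) rows; the
    building block for all overlap queries in the package.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out: list[list[int]] = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


def overlaps_any(
    iv: GenomicInterval, merged: dict[str, np.ndarray]
) -> bool:
    """True iff ``iv`` shares >=1 base with any merged span."""
    spans = merged.get(iv.chrom)
    if spans is None or len(spans) == 0:
        return False
    # rightmost span starting before iv.end
    idx = int(np.searchsorted(spans[:, 0], iv.end, side="left")) - 1
    return idx >= 0 and spans[idx, 1] > iv.start


def filter_blacklist(
    peaks: Sequence[GenomicInterval],
    blacklist: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Drop peaks sharing >=1 base with any blacklisted region.

    Empty blacklist is the identity; input order is preserved.
    """
    if not blacklist:
        return list(peaks)
    merged = merge_intervals(blacklist)
    return [iv for iv in peaks if not overlaps_any(iv, merged)]
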