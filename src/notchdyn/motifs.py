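"""IUPAC motif scanning and head-to-head RBPJ dimer detection.

RBPJ binds the hexamer TGGGAA; at Notch-responsive sites a degenerate form
TGRGAA (R = A/G) is common, and cooperative dimeric complexes assemble on
two half-sites facing each other (plus strand then minus strand) separated
by a 15-17 nt spacer. SP1 (GC-box) motifs mark the promoter-proximal static
class. Matching is substitution-only with a mismatch budget; N never
matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import GenomicInterval

RBPJ_CANONICAL = "TGGGAA"
RBPJ_DEGENERATE = "TGRGAA"
SP1_CONSENSUS = "GGGGCGGGG"
SP1_BUDGET = 1
DIMER_SPACER_MIN = 15
DIMER_SPACER_MAX = 17
DIMER_MISMATCH_BUDGET = 2

# base -> bitmask; N = 0 so it matches no IUPAC class
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 0}
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based match start, plus-strand coordinates
    strand: str
    mismatches: int
    motif_name: str


@dataclass(frozen=True)
class DimerHit:
    first: MotifHit  # plus-strand half-site
    second: MotifHit  # minus-strand half-site
    spacer: int
    total_mismatches: int


@dataclass
class SiteMotifFlags:
    site_id: str
    has_sp1: bool
    has_rbpj_canonical: bool
    has_rbpj_degenerate: bool
    has_dimer: bool


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_BITS[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid sequence character {exc.args[0]!r}") from None


def _motif_bits(motif: str) -> np.ndarray:
    try:
        return np.array([_IUPAC_BITS[b] for b in motif], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None


def _mismatch_profile(seq_bits: np.ndarray, motif_bits: np.ndarray) -> np.ndarray:
    """Mismatch count for the motif at every offset of the sequence."""
    m = len(motif_bits)
    if len(seq_bits) < m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(seq_bits, m)
    return (windows & motif_bits[None, :] == 0).sum(axis=1)


def scan_iupac(
    sequence: str,
    motif: str,
    max_mismatch: int = 0,
    both_strands: bool = True,
    motif_name: str | None = None,
) -> list[MotifHit]:
    """All occurrences of ``motif`` with <= ``max_mismatch`` substitutions.

    Minus-strand hits are matches of the reverse complement reported at
    their plus-strand start offset. Hits are sorted by position, then
    strand (+ before -).
    """
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bases")
    name = motif_name if motif_name is not None else motif
    seq_bits = _encode(sequence.upper())
    hits: list[MotifHit] = []
    strands = [("+", motif)]
    if both_strands:
        strands.append(("-", reverse_complement(motif)))
    for strand, pattern in strands:
        mm = _mismatch_profile(seq_bits, _motif_bits(pattern))
        for pos in np.nonzero(mm <= max_mismatch)[0]:
            hits.append(MotifHit(int(pos), strand, int(mm[pos]), name))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def find_head_to_head_dimers(
    sequence: str,
    half_site: str = RBPJ_CANONICAL,
    spacer_min: int = DIMER_SPACER_MIN,
    spacer_max: int = DIMER_SPACER_MAX,
    max_total_mismatch: int = DIMER_MISMATCH_BUDGET,
) -> list[DimerHit]:
    """Paired half-sites: + strand at i, - strand at j, spacer j-(i+L).

    The spacer (bases between the inner edges of the two half-sites) must
    lie in [spacer_min, spacer_max]; mismatches are summed over both
    half-sites and capped at ``max_total_mismatch``; spacer bases are
    unconstrained.
    """
    if spacer_min < 0 or spacer_max < spacer_min:
        raise ValueError("require 0 <= spacer_min <= spacer_max")
    L = len(half_site)
    seq_bits = _encode(sequence.upper())
    mm_plus = _mismatch_profile(seq_bits, _motif_bits(half_site))
    mm_minus = _mismatch_profile(
        seq_bits, _motif_bits(reverse_complement(half_site))
    )
    hits: list[DimerHit] = []
    cand_plus = np.nonzero(mm_plus <= max_total_mismatch)[0]
    for i in cand_plus:
        for spacer in range(spacer_min, spacer_max + 1):
            j = i + L + spacer
            if j >= len(mm_minus):
                break
            total = int(mm_plus[i]) + int(mm_minus[j])
            if total <= max_total_mismatch:
                hits.append(
                    DimerHit(
                        first=MotifHit(int(i), "+", int(mm_plus[i]), half_site),
                        second=MotifHit(int(j), "-", int(mm_minus[j]), half_site),
                        spacer=spacer,
                        total_mismatches=total,
                    )
                )
    return hits


def flag_sites(
    sites: list[GenomicInterval],
    genome: dict[str, str],
    site_ids: list[str] | None = None,
    sp1_motif: str = SP1_CONSENSUS,
    sp1_budget: int = SP1_BUDGET,
) -> list[SiteMotifFlags]:
    """Per-site motif presence flags used as prediction features.

    Single-motif scans run at 0 mismatches (degeneracy lives in the IUPAC
    letters); SP1 allows ``sp1_budget`` mismatches; the dimer search uses
    its own total budget. All scans cover both strands of the full site
    span.
    """
    if site_ids is None:
        site_ids = [f"site_{i:05d}" for i in range(len(sites))]
    flags: list[SiteMotifFlags] = []
    for site_id, site in zip(site_ids, sites):
        chrom_seq = genome.get(site.chrom)
        if chrom_seq is None:
            raise ValueError(f"chromosome {site.chrom} absent from genome")
        if site.end > len(chrom_seq):
            raise ValueError(
                f"site {site_id} [{site.start},{site.end}) outside "
                f"{site.chrom} (length {len(chrom_seq)})"
            )
        seq = chrom_seq[site.start : site.end]
        canonical = bool(scan_iupac(seq, RBPJ_CANONICAL, 0))
        degenerate = canonical or bool(scan_iupac(seq, RBPJ_DEGENERATE, 0))
        flags.append(
            SiteMotifFlags(
                site_id=site_id,
                has_sp1=bool(scan_iupac(seq, sp1_motif, sp1_budget)),
                has_rbpj_canonical=canonical,
                has_rbpj_degenerate=degenerate,
                has_dimer=bool(find_head_to_head_dimers(seq)),
            )
        )
    return flags
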