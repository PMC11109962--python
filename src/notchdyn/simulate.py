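"""Self-contained synthetic dataset with planted dynamic/static structure.

The generator emits everything the pipeline consumes — genome FASTA, gene
models, replicated peak calls with per-peak p-values, a site x sample count
matrix (optionally materialized as read intervals), an expression table —
plus the planted ground truth, so every stage can be scored against known
labels. The planted structure mirrors the biology the pipeline is built to
detect: a minority class of dynamic sites that bind more strongly, sit
distal to TSSs, carry RBPJ motifs (canonical, degenerate, or head-to-head
dimers), and lose occupancy under GSI, with expression changes coupled to
the genes they regulate; static sites sit promoter-proximal and carry SP1
motifs. Each replicate peak set drops true sites at random and adds weak
background peaks so the k-of-n consensus rule does real work.
"""

from __future__ import annotations

import bisect
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import associate_genes
from .dynamics import CountMatrix
from .genomic_io import (
    GeneModel,
    GenomicInterval,
    ReplicatePeak,
    write_bed,
    write_fasta,
    write_gtf,
)
from .motifs import (
    RBPJ_CANONICAL,
    RBPJ_DEGENERATE,
    SP1_BUDGET,
    SP1_CONSENSUS,
    find_head_to_head_dimers,
    reverse_complement,
    scan_iupac,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic bundle.

    Defaults echo the observed scale of the mouse pre-T-cell dataset
    (~3,500 binding sites with a small dynamic minority) with the dynamic
    fraction mildly enriched so minority-class training is stable.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 12_000_000
    n_genes: int = 1_200
    n_sites: int = 3_500
    frac_dynamic: float = 0.10
    dynamic_log2fc: float = -1.0
    nb_mean_depth: float = 80.0
    nb_dispersion: float = 0.05
    n_replicates: int = 3  # count replicates per condition
    n_peak_replicates: int = 5  # control ChIP replicates emitting peak calls
    peak_dropout: float = 0.15
    background_peak_rate: float = 0.3  # Poisson mean, per true site, per rep
    p_strength_offset: float = 3.0  # extra -log10(p) for dynamic sites
    # class-conditional motif planting
    p_dynamic_canonical: float = 0.6
    p_dynamic_degenerate_only: float = 0.2
    p_dynamic_dimer: float = 0.15
    p_static_sp1: float = 0.5
    p_static_canonical: float = 0.15
    # class-conditional placement
    p_static_promoter: float = 0.7
    p_dynamic_distal: float = 0.8
    distal_min_tss_distance: int = 10_000
    # expression coupling
    p_coupled_deregulated: float = 0.6
    p_background_deregulated: float = 0.1
    emit_reads: bool = False

    def __post_init__(self) -> None:
        for name in (
            "frac_dynamic", "peak_dropout", "p_dynamic_canonical",
            "p_dynamic_degenerate_only", "p_dynamic_dimer", "p_static_sp1",
            "p_static_canonical", "p_static_promoter", "p_dynamic_distal",
            "p_coupled_deregulated", "p_background_deregulated",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 < self.frac_dynamic < 1):
            raise ValueError("frac_dynamic must be in (0, 1)")


@dataclass
class SyntheticBundle:
    config: GeneratorConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    site_ids: list[str]
    sites: list[GenomicInterval]
    replicate_peaks: dict[str, list[ReplicatePeak]]
    counts: CountMatrix
    reads: dict[str, list[GenomicInterval]] | None
    expression: pd.DataFrame  # index gene_id: log2fc, padj
    site_truth: pd.DataFrame  # index site_id
    gene_truth: pd.DataFrame  # index gene_id

    def write(self, outdir) -> None:
        """Materialize the bundle as plain-text standard-format files."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "genome.fa", self.genome)
        write_gtf(out / "genes.gtf", self.genes)
        for rep_id, peaks in self.replicate_peaks.items():
            write_bed(out / f"peaks_{rep_id}.bed", peaks)
        counts = self.counts.counts.copy()
        counts.to_csv(out / "counts.tsv", sep="\t")
        self.counts.conditions.rename("condition").to_csv(
            out / "samples.tsv", sep="\t"
        )
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        self.site_truth.to_csv(out / "site_truth.tsv", sep="\t")
        self.gene_truth.to_csv(out / "gene_truth.tsv", sep="\t")
        with open(out / "config.tsv", "w") as fh:
            for k, v in asdict(self.config).items():
                fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _random_genome(rng, n_chroms: int, length: int) -> dict[str, np.ndarray]:
    return {
        f"chr{i + 1}": _BASES[rng.integers(0, 4, size=length)]
        for i in range(n_chroms)
    }


def _make_genes(rng, chroms: list[str], length: int, n_genes: int) -> list[GeneModel]:
    genes: list[GeneModel] = []
    per_chrom = n_genes // len(chroms)
    gid = 0
    for chrom in chroms:
        margin = 60_000
        tss_positions = np.sort(
            rng.choice(
                np.arange(margin, length - margin, 2_000),
                size=per_chrom,
                replace=False,
            )
        )
        for tss in tss_positions:
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(5_000, 30_000))
            if strand == "+":
                span = GenomicInterval(chrom, int(tss), int(tss) + glen, strand)
            else:
                span = GenomicInterval(chrom, int(tss) - glen + 1, int(tss) + 1, strand)
            exon_len = 300
            exons = [
                GenomicInterval(chrom, span.start, span.start + exon_len),
                GenomicInterval(chrom, span.end - exon_len, span.end),
            ]
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gid:05d}",
                    interval=span,
                    strand=strand,
                    exons=exons,
                )
            )
            gid += 1
    return genes


def _place_sites(
    rng, cfg: GeneratorConfig, genes: list[GeneModel], chroms: list[str]
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Class-conditionally place site intervals; returns (sites, labels)."""
    labels = rng.random(cfg.n_sites) < cfg.frac_dynamic  # True = dynamic
    tss_by_chrom = {
        c: np.sort([g.tss for g in genes if g.interval.chrom == c])
        for c in chroms
    }
    used: dict[str, list[int]] = {c: [] for c in chroms}
    min_gap = 1_000
    sites: list[GenomicInterval] = []
    for i in range(cfg.n_sites):
        dynamic = labels[i]
        placed = None
        # the placement class is decided once; retries only move the site
        u = rng.random()
        for _ in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            tss = tss_by_chrom[chrom]
            if not dynamic and u < cfg.p_static_promoter and len(tss):
                anchor = int(tss[rng.integers(len(tss))])
                pos = anchor + int(rng.normal(0, 800))
            elif dynamic and u < cfg.p_dynamic_distal:
                pos = int(rng.integers(1_000, cfg.chrom_length - 1_000))
                if len(tss):
                    j = np.searchsorted(tss, pos)
                    near = min(
                        abs(pos - int(tss[k]))
                        for k in (max(j - 1, 0), min(j, len(tss) - 1))
                    )
                    if near < cfg.distal_min_tss_distance:
                        continue
            else:
                pos = int(rng.integers(1_000, cfg.chrom_length - 1_000))
            if pos < 1_000 or pos > cfg.chrom_length - 1_000:
                continue
            arr = used[chrom]
            lo = bisect.bisect_left(arr, pos - min_gap)
            hi = bisect.bisect_right(arr, pos + min_gap)
            if hi > lo:
                continue
            placed = (chrom, pos)
            break
        if placed is None:
            raise RuntimeError("could not place all sites; genome too crowded")
        chrom, pos = placed
        bisect.insort(used[chrom], pos)
        width = int(rng.integers(200, 401))
        sites.append(GenomicInterval(chrom, pos - width // 2, pos + width - width // 2))
    return sites, labels


_WINDOW_FLAGS = ("sp1", "canonical", "degenerate", "dimer")


def _window_flags(seq: str) -> dict[str, bool]:
    canonical = bool(scan_iupac(seq, RBPJ_CANONICAL, 0))
    return {
        "sp1": bool(scan_iupac(seq, SP1_CONSENSUS, SP1_BUDGET)),
        "canonical": canonical,
        "degenerate": canonical or bool(scan_iupac(seq, RBPJ_DEGENERATE, 0)),
        "dimer": bool(find_head_to_head_dimers(seq)),
    }


def _plant_motifs(
    rng, genome: dict[str, np.ndarray], sites, labels, cfg: GeneratorConfig
) -> pd.DataFrame:
    """Scrub each site window of spurious motifs, then plant per class.

    Windows are redrawn until the scanned flags equal the intended flags,
    so re-scanning the emitted FASTA recovers the planted flags exactly.
    """
    rows = []
    for i, (site, dynamic) in enumerate(zip(sites, labels)):
        u = rng.random()
        intended = {k: False for k in _WINDOW_FLAGS}
        insert = None
        if dynamic:
            if u < cfg.p_dynamic_canonical:
                insert = RBPJ_CANONICAL
                intended.update(canonical=True, degenerate=True)
            elif u < cfg.p_dynamic_canonical + cfg.p_dynamic_degenerate_only:
                insert = "TGAGAA"
                intended.update(degenerate=True)
            elif (
                u
                < cfg.p_dynamic_canonical
                + cfg.p_dynamic_degenerate_only
                + cfg.p_dynamic_dimer
            ):
                insert = "DIMER"
                intended.update(canonical=True, degenerate=True, dimer=True)
        else:
            if u < cfg.p_static_sp1:
                insert = SP1_CONSENSUS
                intended.update(sp1=True)
            elif u < cfg.p_static_sp1 + cfg.p_static_canonical:
                insert = RBPJ_CANONICAL
                intended.update(canonical=True, degenerate=True)
        arr = genome[site.chrom]
        width = len(site)
        for _ in range(100):
            window = _BASES[rng.integers(0, 4, size=width)]
            if insert is not None:
                if insert == "DIMER":
                    spacer = int(rng.integers(15, 18))
                    motif = (
                        RBPJ_CANONICAL
                        + "".join(
                            "ACGT"[b] for b in rng.integers(0, 4, size=spacer)
                        )
                        + reverse_complement(RBPJ_CANONICAL)
                    )
                else:
                    motif = insert
                off = width // 2 - len(motif) // 2
                window[off : off + len(motif)] = np.frombuffer(
                    motif.encode(), dtype=np.uint8
                )
            if _window_flags(window.tobytes().decode()) == intended:
                break
        else:
            raise RuntimeError(f"could not realize motif flags for site {i}")
        arr[site.start : site.end] = window
        rows.append(
            {
                "has_sp1": intended["sp1"],
                "has_rbpj_canonical": intended["canonical"],
                "has_rbpj_degenerate": intended["degenerate"],
                "has_dimer": intended["dimer"],
            }
        )
    return pd.DataFrame(rows)


def _replicate_peaks(
    rng, cfg: GeneratorConfig, sites, strength: np.ndarray
) -> dict[str, list[ReplicatePeak]]:
    peaks: dict[str, list[ReplicatePeak]] = {}
    n_bg = cfg.background_peak_rate * cfg.n_sites
    chroms = sorted({s.chrom for s in sites})
    for r in range(cfg.n_peak_replicates):
        rep_id = f"ctrl_rep{r + 1}"
        rep_peaks: list[ReplicatePeak] = []
        keep = rng.random(len(sites)) >= cfg.peak_dropout
        rep_strength = np.clip(strength + rng.normal(0, 1.0, len(sites)), 2.2, 290)
        for i, site in enumerate(sites):
            if not keep[i]:
                continue
            jitter_l = int(rng.integers(0, 101))
            jitter_r = int(rng.integers(0, 101))
            iv = GenomicInterval(
                site.chrom, max(site.start - jitter_l, 0), site.end + jitter_r
            )
            rep_peaks.append(
                ReplicatePeak(iv, float(10.0 ** -rep_strength[i]), rep_id)
            )
        for _ in range(int(rng.poisson(n_bg))):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, cfg.chrom_length - 500))
            width = int(rng.integers(200, 401))
            p = float(10.0 ** -rng.uniform(2.0, 5.0))
            rep_peaks.append(
                ReplicatePeak(GenomicInterval(chrom, start, start + width), p, rep_id)
            )
        rep_peaks.sort(key=lambda pk: (pk.interval.chrom, pk.interval.start))
        peaks[rep_id] = rep_peaks
    return peaks


def _draw_counts(
    rng, cfg: GeneratorConfig, site_ids, labels
) -> tuple[CountMatrix, np.ndarray]:
    n = len(site_ids)
    mu_control = np.full(n, cfg.nb_mean_depth)
    effect = np.where(labels, cfg.dynamic_log2fc, 0.0)
    mu_gsi = mu_control * 2.0 ** effect
    sample_ids, conditions, columns = [], {}, []
    disp_n = 1.0 / cfg.nb_dispersion
    for cond, mu in (("control", mu_control), ("GSI", mu_gsi)):
        for r in range(cfg.n_replicates):
            sid = f"{cond}_rep{r + 1}"
            lib = rng.uniform(0.7, 1.3)
            m = mu * lib
            p = disp_n / (disp_n + m)
            columns.append(rng.negative_binomial(disp_n, p))
            sample_ids.append(sid)
            conditions[sid] = cond
    counts = pd.DataFrame(
        np.column_stack(columns), index=site_ids, columns=sample_ids
    )
    return (
        CountMatrix(counts=counts, conditions=pd.Series(conditions)),
        effect,
    )


def _materialize_reads(
    rng, sites, site_ids, cm: CountMatrix, read_length: int = 150
) -> dict[str, list[GenomicInterval]]:
    """Place exactly count_ij reads overlapping site i for sample j."""
    reads: dict[str, list[GenomicInterval]] = {}
    for sample in cm.counts.columns:
        sample_reads: list[GenomicInterval] = []
        col = cm.counts[sample]
        for site_id, site in zip(site_ids, sites):
            k = int(col[site_id])
            if k == 0:
                continue
            lo = max(site.start - read_length + 1, 0)
            hi = site.end - 1
            starts = rng.integers(lo, hi + 1, size=k)
            sample_reads.extend(
                GenomicInterval(site.chrom, int(s), int(s) + read_length)
                for s in starts
            )
        reads[sample] = sample_reads
    return reads


def _expression(
    rng,
    cfg: GeneratorConfig,
    genes: list[GeneModel],
    sites,
    site_ids,
    labels,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    dynamic_sites = [s for s, lab in zip(sites, labels) if lab]
    dynamic_ids = [i for i, lab in zip(site_ids, labels) if lab]
    assoc = associate_genes(dynamic_sites, genes, site_ids=dynamic_ids)
    dynamic_assoc_genes = set().union(*[a.gene_ids for a in assoc]) if assoc else set()
    rows, truth_rows = [], []
    for g in genes:
        coupled = False
        if g.gene_id in dynamic_assoc_genes:
            coupled = rng.random() < cfg.p_coupled_deregulated
        deregulated = coupled or rng.random() < cfg.p_background_deregulated
        if deregulated:
            magnitude = 1.0 + abs(rng.normal(1.0, 0.5))
            # coupled genes lose expression when Notch is blocked
            sign = -1.0 if coupled or rng.random() < 0.5 else 1.0
            log2fc = sign * magnitude
            padj = float(10.0 ** -rng.uniform(2.0, 6.0))
        else:
            log2fc = float(rng.normal(0.0, 0.3))
            padj = float(rng.uniform(0.05, 1.0))
        rows.append({"gene_id": g.gene_id, "log2fc": log2fc, "padj": padj})
        truth_rows.append(
            {
                "gene_id": g.gene_id,
                "dynamic_associated": g.gene_id in dynamic_assoc_genes,
                "coupled": coupled,
                "deregulated": deregulated,
            }
        )
    expression = pd.DataFrame(rows).set_index("gene_id")
    gene_truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return expression, gene_truth


# ---------------------------------------------------------------------------
# entry points
# ---------------------------------------------------------------------------


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Generate the full synthetic bundle for one seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome_arr = _random_genome(rng, cfg.n_chroms, cfg.chrom_length)
    genes = _make_genes(rng, chroms, cfg.chrom_length, cfg.n_genes)
    sites, labels = _place_sites(rng, cfg, genes, chroms)
    site_ids = [f"true_{i:05d}" for i in range(cfg.n_sites)]
    motif_truth = _plant_motifs(rng, genome_arr, sites, labels, cfg)

    # per-site binding strength on the -log10(p) scale; dynamic sites are
    # systematically stronger
    strength = rng.uniform(4.0, 10.0, cfg.n_sites)
    strength = strength + np.where(labels, cfg.p_strength_offset, 0.0)

    replicate_peaks = _replicate_peaks(rng, cfg, sites, strength)
    cm, effect = _draw_counts(rng, cfg, site_ids, labels)
    reads = (
        _materialize_reads(rng, sites, site_ids, cm) if cfg.emit_reads else None
    )
    expression, gene_truth = _expression(rng, cfg, genes, sites, site_ids, labels)

    site_truth = pd.DataFrame(
        {
            "site_id": site_ids,
            "chrom": [s.chrom for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "label": np.where(labels, "dynamic", "static"),
            "planted_log2fc": effect,
            "strength": strength,
        }
    ).set_index("site_id")
    site_truth = pd.concat(
        [site_truth, motif_truth.set_index(site_truth.index)], axis=1
    )

    genome = {c: genome_arr[c].tobytes().decode() for c in chroms}
    return SyntheticBundle(
        config=cfg,
        genome=genome,
        genes=genes,
        site_ids=site_ids,
        sites=sites,
        replicate_peaks=replicate_peaks,
        counts=cm,
        reads=reads,
        expression=expression,
        site_truth=site_truth,
        gene_truth=gene_truth,
    )


def truth_compare(
    predicted: pd.Series, truth: pd.Series, scores: pd.Series | None = None
) -> dict[str, float]:
    """Confusion counts plus TPR/FPR (and AUC when scores are given).

    ``predicted`` and ``truth`` hold "dynamic"/"static" per site_id;
    dynamic is the positive class.
    """
    if set(predicted.index) != set(truth.index):
        raise ValueError("site_id mismatch between predictions and truth")
    predicted = predicted.loc[truth.index]
    pos = truth == "dynamic"
    tp = int(((predicted == "dynamic") & pos).sum())
    fn = int(((predicted == "static") & pos).sum())
    fp = int(((predicted == "dynamic") & ~pos).sum())
    tn = int(((predicted == "static") & ~pos).sum())
    out = {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "tpr": tp / (tp + fn) if tp + fn else float("nan"),
        "fpr": fp / (fp + tn) if fp + tn else float("nan"),
    }
    if scores is not None:
        from sklearn.metrics import roc_auc_score

        y = pos.astype(int)
        if y.nunique() == 2:
            out["auc"] = float(roc_auc_score(y, scores.loc[truth.index]))
        else:
            out["auc"] = float("nan")
    return out


def acetylation_peaks(
    bundle: SyntheticBundle, seed: int = 0
) -> tuple[list[GenomicInterval], list[float]]:
    """Synthetic H3K27ac-like peaks: dense around dynamic sites.

    Dynamic sites nucleate clusters of several strong peaks within +-10 kb;
    static sites sometimes carry a lone peak; a sparse background covers the
    rest of the genome. Intended for exercising the cluster stitching and
    class-intersection steps, not for realism.
    """
    rng = np.random.default_rng(seed)
    peaks: list[GenomicInterval] = []
    signals: list[float] = []
    for site, label in zip(bundle.sites, bundle.site_truth["label"]):
        if label == "dynamic":
            for _ in range(int(rng.integers(4, 9))):
                center = site.midpoint + int(rng.integers(-10_000, 10_001))
                width = int(rng.integers(500, 1_500))
                start = max(center - width // 2, 0)
                peaks.append(GenomicInterval(site.chrom, start, start + width))
                signals.append(float(rng.uniform(50, 150)))
        elif rng.random() < 0.3:
            width = int(rng.integers(500, 1_500))
            start = max(site.midpoint - width // 2, 0)
            peaks.append(GenomicInterval(site.chrom, start, start + width))
            signals.append(float(rng.uniform(5, 30)))
    n_background = max(len(bundle.sites) // 4, 10)
    chroms = sorted(bundle.genome)
    for _ in range(n_background):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, bundle.config.chrom_length - 2_000))
        width = int(rng.integers(500, 1_500))
        peaks.append(GenomicInterval(chrom, start, start + width))
        signals.append(float(rng.uniform(5, 30)))
    return peaks, signals
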