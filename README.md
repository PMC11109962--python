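# notchdyn

Tools for telling **dynamic** (Notch-responsive) from **static** RBPJ/CSL
binding sites in replicated ChIP-seq data, and for predicting responsiveness
from binding features alone.

RBPJ is the DNA-binding hub of Notch signalling: its nuclear levels barely
change, but when the Notch intracellular domain (NICD) is released it converts
RBPJ complexes from repressive to activating. Genome-wide, only a minority of
RBPJ sites actually respond to Notch perturbation — occupancy drops when
γ-secretase inhibitor (GSI) blocks NICD release (log₂FC < −0.5) or rebounds on
GSI washout (log₂FC > 0.5). These *dynamic* sites are stronger, sit distal to
transcription start sites, carry RBPJ motifs (canonical `TGGGAA`, degenerate
`TGRGAA`, or head-to-head dimer pairs spaced 15–17 nt apart), and drive the
transcriptional Notch response; *static* sites are promoter-proximal,
SP1-marked, and transcriptionally inert under Notch perturbation.

The package implements the full analysis chain:

1. **genomic_io** — BED/narrowPeak/GTF/FASTA readers and writers around a
   single 0-based half-open coordinate convention; ENCODE-blacklist filtering.
2. **consensus** — k-of-n replicate validation of peak calls with
   Fisher-combined p-values and weak/stringent thresholds (w = 1e-6,
   s = 1e-10), plus min–max normalization of site significance on the
   −log₁₀ scale.
3. **dynamics** — windowed read counting, median-of-ratios size factors, and
   the ±0.5 log₂FC dynamic/static rule.
4. **motifs** — IUPAC motif scanning with mismatch budgets on both strands,
   and the head-to-head RBPJ dimer search (15–17 nt spacer, ≤2 total
   mismatches).
5. **annotation** — distance to nearest TSS, positional categories (promoter,
   UTRs, gene body, downstream, intergenic), and basal-plus-extension
   regulatory-domain gene association (5 kb up / 1 kb down, ≤1 Mb extension).
6. **model** — the five-feature random forest (normalized peak p-value,
   positional category, SP1 / canonical-RBPJ / degenerate-RBPJ motif flags)
   with stratified 85/15 and 80/20 splits and the >65%-dynamic-TPR candidate
   selection rule.
7. **enrichment** — deregulated-gene calling (|log₂FC| > 1, adjusted
   p < 0.05), gene-class assignment (a gene with any dynamic site is
   dynamic), hypergeometric enrichment, median-split controls.
8. **clusters** — super-enhancer-style stitching (12.5 kb) and rank-signal
   inflection cut, intersected with site classes.
9. **simulate** — a fully self-contained synthetic data generator with
   planted ground truth (genome, genes, replicated peaks, negative-binomial
   counts, coupled expression), used by every test.

## Worked example

Generate a default-scale synthetic dataset (3,500 planted sites, 10%
dynamic) and run the whole chain against its planted truth:

```python
from notchdyn import GeneratorConfig, generate, run_pipeline

bundle = generate(GeneratorConfig(seed=1))
result = run_pipeline(bundle, model_seed=1)

n_dyn = sum(d.label == "dynamic" for d in result.dynamics)
print(f"consensus sites: {len(result.consensus)}")
print(f"dynamic / static: {n_dyn} / {len(result.dynamics) - n_dyn}")
cvt = result.classification_vs_truth
print(f"occupancy classification vs planted truth: "
      f"TPR={cvt['tpr']:.3f} FPR={cvt['fpr']:.3f}")
vm, tm = result.validation_metrics, result.test_metrics
print(f"selected forest (validation): accuracy={vm['accuracy']:.3f} "
      f"dynamic-TPR={vm['tpr_dynamic']:.3f} AUC={vm['auc']:.3f}")
print(f"held-out test: accuracy={tm['accuracy']:.3f} AUC={tm['auc']:.3f}")
for e in result.enrichment:
    print(f"{e.group_name} genes: {e.n_overlap}/{e.n_group} deregulated, "
          f"fold={e.fold_enrichment:.2f}, p={e.p_value:.2e}")
```

which prints:

```text
consensus sites: 3409
dynamic / static: 372 / 3034
occupancy classification vs planted truth: TPR=0.932 FPR=0.027
selected forest (validation): accuracy=0.865 dynamic-TPR=0.587 AUC=0.789
held-out test: accuracy=0.873 AUC=0.885
dynamic genes: 262/463 deregulated, fold=1.91, p=2.15e-59
static genes: 93/732 deregulated, fold=0.43, p=1.00e+00
```

Reading this: the 3-of-5 replicate consensus recovers 3,409 of the 3,500
planted sites (plus a handful of background survivors); the ±0.5 log₂FC rule
recovers planted dynamic sites at 93% sensitivity with a 2.7% false-positive
rate; the selected forest separates the classes well beyond chance (test AUC
0.89; the validation dynamic-TPR varies by dataset and averages ~0.67–0.71
over ten seeds); and deregulated genes concentrate almost entirely in the
dynamic-site-associated gene class (fold enrichment 1.9 vs 0.4), reproducing
the expression coupling the generator plants.

The same stages are scriptable from the shell via the `nrp` command
(`nrp simulate`, `nrp consensus`, `nrp dynamics`, `nrp motifs`,
`nrp annotate`, `nrp associate`, `nrp features`, `nrp train`, `nrp predict`,
`nrp enrich`, `nrp clusters`, `nrp filter-blacklist`).

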