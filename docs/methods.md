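# Methods

## The problem and the model

Notch signalling acts through a transcription factor, RBPJ (CSL), whose
nuclear abundance is roughly constant; what changes with pathway activity is
the composition of the complexes it nucleates. Genome-wide, only a minority
of RBPJ binding sites responds to Notch perturbation. This package classifies
each replicate-validated binding site as **dynamic** (occupancy falls when
γ-secretase inhibition removes NICD, or rises on inhibitor washout) or
**static**, and then asks two questions: do dynamic sites drive the
transcriptional response, and can responsiveness be predicted from binding
features alone?

The operative definitions, applied verbatim throughout:

- *Dynamic site*: normalized occupancy log₂FC < −0.5 under GSI treatment, or
  > +0.5 after GSI washout, strict inequalities. Everything else is static.
  The rule is fold-change-only; no significance filter is applied to the
  binding change itself.
- *Deregulated gene*: expression log₂FC > 1 or < −1 with adjusted p < 0.05,
  strict inequalities; missing adjusted p means not significant.
- *Dynamic gene class*: a gene associated with at least one dynamic site is
  dynamic even if it also carries static sites.

## Replicate consensus

Per-replicate peak calls are grouped by transitive closure of ≥1 bp overlap
(computed per chromosome by a sorted sweep, which is exactly the transitive
closure for interval overlap). A group becomes a consensus site iff

1. it is supported by at least `min_support` distinct replicates (3 of 5 for
   the TF's control replicates; 3 of 4 in histone-mark mode), and
2. the Fisher combination of one representative p-value per replicate (the
   most significant peak each replicate contributes, to avoid
   pseudo-replication) is ≤ the weak threshold w = 1e-6 — or some single
   constituent peak is ≤ the stringent threshold s = 1e-10, which rescues the
   group regardless of the combined value.

This is a deliberate re-specification of the published replicate-validation
tool's weak/stringent logic, not a bit-exact reproduction: the operative
filter is the k-of-n rule, and the two thresholds are honoured as stated.
Combined significance is min–max normalized on the −log₁₀ scale (raw
p-values cluster degenerately near zero and would destroy dynamic range);
the most significant site maps to 1.

## Occupancy quantification

Reads are counted over each site extended by a flank (0 bp for the TF's own
sites; 500 bp for chromatin-mark matrices, matching the ±500 bp detection
window) with ≥1 bp overlap. Normalization is median-of-ratios: the reference
per site is the geometric mean across samples (over sites positive
everywhere), a sample's size factor is the median ratio to that reference.
Fold changes are unshrunk: log₂((mean normalized treated + 1) /
(mean normalized control + 1)). The pseudocount of 1 (configurable) guards
the log at zero counts; at the default depth (~80 reads/site) its bias is
negligible. Note one consequence of median-of-ratios: scaling one library by
c multiplies its factor by c only up to the c^(1/m) share absorbed by the
geometric-mean reference — factor *ratios*, and hence fold changes, are the
invariant quantities.

## Motif model

Matching is substitution-only over ACGTN (N never matches), both strands,
with IUPAC degeneracy in the pattern: canonical RBPJ `TGGGAA`, degenerate
`TGRGAA` (so every canonical hit is a degenerate hit), SP1 GC-box consensus
`GGGGCGGGG` with ≤1 mismatch. Single-motif feature scans use 0 mismatches —
the degeneracy lives in the IUPAC letter, not the budget. The SP1 consensus
with a 1-mismatch budget replaces the position-weight-matrix scan of an
external database matrix; a user-supplied PWM is out of scope here, and the
consensus captures the GC-box class signal the feature needs.

Head-to-head dimer (sequence-paired-site) search: a plus-strand half-site at
i paired with a minus-strand half-site at j, spacer j − (i+6) in [15, 17],
spacer bases unconstrained, and a **total** mismatch budget of 2 across both
half-sites. The published description caps mismatches at two without saying
per-half-site or total; total is the conservative reading and is
configurable. The spacer is measured between the inner edges of the two
hexamers, the convention of the paired-site literature.

## Position and gene association

The site midpoint (not any-overlap) drives both categorization and
association — deterministic single assignment. Categories are assigned with
precedence promoter > 5′UTR > 3′UTR > gene body > downstream > intergenic;
intron and exon are never distinguished (both are "gene body"). The promoter
window defaults to TSS ± 3 kb and the downstream window to 3 kb — the
defaults of the annotation tooling this mirrors; both configurable.

Gene association uses a basal-plus-extension regulatory domain: basal = 5 kb
upstream / 1 kb downstream of the TSS in strand orientation; each edge then
extends outward up to 1 Mb but stops at the nearest neighbouring basal
domain. A neighbour whose basal domain overlaps a gene's own basal span
suppresses extension entirely on that side (extension never enters a basal
domain; a gene's own basal span is always kept). A site associates with
every gene whose domain contains its midpoint. Nearest-TSS ties break to the
lexicographically smaller gene id for reproducibility.

## The responsiveness model

Five features per site: min–max-normalized combined significance, positional
category (one-hot over the closed six-category set), and three motif
booleans (SP1, canonical RBPJ, degenerate RBPJ). Splits are stratified by
label and fully seed-determined: 15% test, then 20% of the remainder for
validation (0.68 / 0.17 / 0.15 of the total). The forest uses 500 trees,
√p features per split, no depth cap — the standard defaults of the ensemble
implementation — with class weights inverse to class frequency, since the
dynamic class is a ~10% minority (weighting can be disabled). Candidate
forests are trained on consecutive seeds; the first whose mean dynamic-class
TPR over the validation set (and an external set when given, averaging the
two) exceeds 0.65 is selected; if none qualifies the best one is returned
flagged unqualified. Prediction thresholds the dynamic-class probability at
0.5. Accuracy is correct/total; per-class TPR is correct-in-class/class
size; AUC is the rank statistic over dynamic-class probabilities.

## The synthetic data generator

The generator emulates the statistical structure the pipeline is built to
detect, at the scale of the mouse pre-T-cell dataset (3,500 sites; the
dynamic fraction default of 0.10 is mildly enriched over the observed ~4.5%
so minority-class training is stable at desk scale):

- **Genome and genes**: i.i.d. random sequence, 4 × 12 Mb chromosomes,
  1,200 two-exon genes with random strands and TSS-sorted placement.
- **Sites**: width 200–400 bp, ≥1 kb apart. Static sites are
  promoter-anchored (TSS + N(0, 800 bp)) with probability 0.7; dynamic sites
  are placed >10 kb from any TSS with probability 0.8; the placement class is
  decided once per site and retries only move the site, so the bias is
  realized even where promoters crowd.
- **Motifs**: each site window is redrawn until free of spurious RBPJ / SP1 /
  dimer matches, then the class-conditional motif is planted (dynamic:
  canonical 0.6, degenerate-only 0.2, dimer 0.15; static: SP1 0.5, canonical
  0.15). Re-scanning the emitted FASTA therefore recovers the planted flags
  exactly — on unscrubbed random sequence the canonical hexamer alone would
  appear spuriously in ~15% of windows and the flags would not be clean
  truth.
- **Peaks**: five control replicates; each drops every true site
  independently with probability 0.15 (so the 3-of-5 rule does real work:
  ~97% of true sites survive) and adds weak Poisson background peaks
  (rate 0.3 per true site) that fail either support or the weak threshold.
  Per-replicate −log₁₀ p = per-site strength (Uniform(4, 10), plus an offset
  of 3 for dynamic sites — binding is stronger at dynamic sites) + N(0, 1).
- **Counts**: negative binomial, dispersion 0.05, mean depth 80, three
  replicates per condition, per-sample library factors Uniform(0.7, 1.3);
  dynamic sites' treated mean is scaled by 2^(−1) (the planted effect).
  Optionally the counts are materialized as read intervals placed so that
  re-counting reproduces the matrix exactly.
- **Expression**: genes associated with a dynamic site (by the package's own
  association model) are deregulated with probability 0.6 (downward, as GSI
  switches targets off), all others with background probability 0.1.

What the generator does **not** emulate: fragment-length and GC biases,
peak-shape structure, dispersion trends, correlated replicates, chromatin
state, or any real genome's gene density and repeat content. Passing tests
demonstrate that the pipeline recovers planted structure under its own
statistical assumptions, not performance on real libraries.

## Numerical choices and problem sizes

- p-values of exactly 0 are floored to 1e-300 on input; combined p-values are
  floored at the smallest positive double. Strength draws are capped so
  Fisher combination never underflows.
- Degenerate min–max normalization (all values equal) maps to all-zero with a
  warning rather than an error.
- Median-split ties go to the bottom half ("> median" is strict).
- The test suite runs its property checks at reduced problem sizes chosen as
  the package's own desk-scale defaults: parameter-recovery and null checks
  use 250–400-site bundles over 20 (or 5) seeds; the model-selection check
  runs the full default 3,500-site bundle over ten seeds; the permutation
  null is asserted on the mean AUC of five permutations of a ≥2,000-row
  table evaluated on held-out data, since a single permutation's held-out
  AUC has a standard deviation of ~0.04 at that size.
- End-to-end determinism: a bundle is a pure function of its config (one
  `numpy` Generator seeded once); splits, candidate training and selection
  are pure functions of their seeds.

## Known limitations

- The replicate-consensus rule is a simplification of the published
  multi-stage validation tool; borderline groups can differ from that tool's
  output. Acceptance rests on synthetic truth, not on reproducing its exact
  site lists.
- Whether the published normalization min–maxed raw or log-transformed
  p-values is unstated; this package uses −log₁₀ (see above) and documents
  the divergence risk.
- The enrichment universe is the set of genes present in the expression
  table — the most restrictive defensible choice; the published universe is
  unprinted. Direction-pooled "deregulated" is the default, with
  direction-specific flags.
- Training labels in the end-to-end pipeline come from the occupancy
  classification, which at the default noise level mislabels ~2–3% of static
  sites as dynamic; since dynamic sites are a small minority, roughly a
  fifth of the "dynamic" training class is label noise, and measured
  dynamic-TPR is bounded well below 1 even for a perfect feature model. This
  mirrors the observational setting the method is designed for.
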