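# zfpkit

Integration analyses for multi-omics studies of zinc-finger proteins
(ZFPs). Hundreds of ZFPs are candidate RNA-binding proteins, but their
RNA targets and regulatory roles are mostly uncharacterized. Studies
that profile them combine knockdown RNA-seq (differential expression,
splicing and polyadenylation), eCLIP (RNA binding sites), Cut&Run (DNA
binding), RBNS (in vitro sequence specificity), SLAM-seq (RNA decay),
Ribo-STAMP (ribosome association) and tethering reporters. The
standard upstream tools end at per-assay tables; zfpkit implements the
downstream computations that turn those tables into biological calls:

* significant-event calling (FDR < 0.05, |FC| > 20% or |ΔΨ| > 0.2) and
  **batch-residual outlier detection** — OLS of event counts on batch
  indicators, flagging knockdowns with externally studentized residual
  p < 0.05 and residual > +20% of the batch prediction;
* **eCLIP window annotation** into transcript feature classes
  (5'UTR/CDS/3'UTR/intron, splice-site ADJ ≤ 50 bp / PROX ≤ 300 bp) and
  feature enrichment odds ratios with one-sided Fisher tests;
* **RBNS motif derivation** — k-mer enrichment R = freq_pulldown /
  freq_input, priority alignment of the top 20 k-mers to the most
  enriched one (1 mismatch and/or 1 offset, or 2 mismatches), and an
  enrichment-weighted PWM with edge trimming;
* **protein feature calling** — ARM-like loci (K/R frequency > 0.5 in
  5-aa windows), disordered regions (score > 0.4), occlusion-derived
  RNA-binding domains (Z < −1) and their overlap classes;
* **set-overlap integration** of binding targets with
  knockdown-responsive gene sets (exact hypergeometric/Fisher, Jaccard,
  cassette-exon proximity counts at ≤ 50 bp);
* **dual DNA/RNA binder analysis** — DRBP classification (> 500 unique
  genes at both levels, intergenic peaks > 100 kb excluded), signed
  DNA→RNA distances, metagene density over 101 percent-of-transcript
  bins, and TSS/TTS-proximal (2%) Mann-Whitney comparisons;
* **SLAM-seq kinetics** — CPM > 5 filtering, first-order decay fits
  y(t) = e^(−kt) with half-life ln 2 / k and R² > 0.6 gating, and
  half-life shift tests;
* **Ribo-STAMP EPR** (edits per exonic read) with 2-vs-2 t-tests at
  BH FDR < 0.1, and **tethering-reporter** one-tailed hit calling.

A first-class synthetic-data module generates every input shape with
planted ground truth (batch effects, feature-class enrichment, sequence
motifs, exponential decay, editing and luminescence effects), so the
whole pipeline is testable without any external download.

## Worked example

Recover a planted 8-fold 3'UTR binding preference
(`examples/02_binding_annotation.py`):

```python
from zfpkit import binding, simulate as sim

cfg = sim.SimConfig(seed=1, n_genes=100)
genes = sim.make_annotation(cfg)
ip, background, _, _ = sim.simulate_binding(
    cfg, genes, planted_feature="3'UTR", planted_or=8.0, n_windows=5000)
binding.annotate_windows(ip, genes)
binding.annotate_windows(background, genes)
enr = binding.feature_enrichment_odds(ip, background, "3'UTR")
```

which prints

```
3'UTR enrichment: OR = 8.15, log2(OR) = 3.03, one-sided Fisher p = 0.00e+00
planted odds ratio was 8 (log2 = 3.0)
```

The IP windows fall in the 3'UTR 43.7% of the time against a ~9%
genomic background, giving a 2×2 odds ratio of 8.15 — the planted
enrichment, recovered through the midpoint classifier and the Fisher
machinery. The other scripts in `examples/` walk through batch-residual
outliers, RBNS motifs, protein features, target-set overlap, dual-binder
geometry, SLAM kinetics, and tethering/EPR statistics the same way; each
prints the numbers it computes and what they mean.

There is also a thin CLI for end-to-end runs:

```bash
zfpkit all --seed 1 --out run1     # simulate -> annotate -> integrate -> report
zfpkit annotate-windows --windows w.bed --annotation genes.bed12
```

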