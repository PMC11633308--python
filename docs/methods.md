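# Methods

zfpkit implements the bespoke integration computations used to
characterize the DNA/RNA-binding and regulatory activity of zinc-finger
proteins (ZFPs) from knockdown RNA-seq, eCLIP, Cut&Run, RBNS, SLAM-seq,
Ribo-STAMP, protein feature tracks, and tethering reporters. Upstream
read processing (alignment, peak/window calling, differential testing)
is out of scope: the package consumes those tools' output tables and
implements everything downstream of them, together with a synthetic-data
module that emulates every input shape with planted ground truth.

## Coordinate frame

All intervals are 0-based half-open (BED convention); GTF input is
converted on read. A `GeneModel` carries exon structure, a
5'UTR/CDS/3'UTR partition of exonic space, and strand-aware TSS/TTS.
Splice sites are the exon/intron boundary coordinates, with the donor
(5' splice site) at the transcriptionally upstream end of each intron.
Unstranded (`.`) windows are treated as `+` with a warning, since the
signed-distance and metagene operations require an orientation.

## Knockdown event calling and batch residuals

Significant events use the thresholds: DEG, FDR < 0.05 and |FC| > 20%
(|log2FC| > log2 1.2); ASE and APAE, FDR < 0.05 and |ΔΨ| > 0.2. All
inequalities are strict; records with missing FDR are excluded and
tallied.

Because knockdown batches differ ~10-fold in baseline event counts, a
knockdown is only flagged relative to its batch. Counts are regressed on
batch indicators by ordinary least squares with cell-means coding, so
the fitted value is the batch mean — the simplest model consistent with
"counts on batch" regression. The per-dataset test is the externally
studentized residual referred to t(n − k − 1), the standard OLS outlier
test; two-sided by default with a one-sided option. A dataset is
high-residual when p < 0.05 **and** the residual exceeds +20% of the
predicted count. The overall model fit is reported as the one-way F-test
but never used for flagging. Batches with a single dataset are rejected
(no within-batch variance). On null simulations the conjunction flags
well under 5% of datasets: for large batch means the +20% effect
requirement is many Poisson standard deviations and dominates the test.

## eCLIP window annotation and enrichment

Each window is assigned exactly one feature class by the position of its
midpoint (deterministic and window-length-robust; the upstream window
caller does not publish its own assignment rule). Splice-site classes
take precedence over containment classes: ADJ (≤ 50 bp from a splice
site) beats PROX (≤ 300 bp); when both a donor and an acceptor qualify
at the same level the nearer wins, exact ties to the acceptor; otherwise
the class is the feature containing the midpoint, `noncoding` for genes
without a CDS, and `intergenic` off-gene.

Feature enrichment is a 2×2 table of in/out-of-class counts for IP
versus a caller-supplied background window set (background generation is
the window caller's job; the synthetic module supplies a uniform
transcript sample). The odds ratio is (ip_in/ip_out)/(bg_in/bg_out) with
a Haldane–Anscombe 0.5 correction applied only when a cell is zero; the
p-value is the one-sided (greater) Fisher exact test on the uncorrected
table. Binding breadth counts unique bound transcripts; "widespread"
means ≥ 500, while the dual-binder rule below uses the strict > 500.

## RBNS motif derivation

Pentamer (k configurable) counts use a sliding window over the full
reads of each pool; reads with non-ACGU(T) symbols are skipped and
tallied, and T is read as U. Frequencies are computed after adding a
pseudocount of 1 to every k-mer over the union of both pools — the
smallest perturbation that keeps the enrichment R = freq_pd/freq_in
finite for k-mers absent from the input; for abundant k-mers the effect
is negligible. The table is sorted by R, ties broken lexicographically.

The top 20 k-mers are aligned to the most enriched one (the anchor)
with budgets: zero offset with ≤ 2 mismatches, or one offset (|offset| =
1) with ≤ 1 mismatch; priority order exact > 1 mismatch > 1 offset >
1 offset + 1 mismatch > 2 mismatches. The two budget phrasings in the
source protocol disagree at the lowest priority ("2 mismatches" versus
"2 offsets"); since |offset| is capped at 1 for a pair, the 2-mismatch
reading is the only self-consistent one and is what is implemented.
Within a category, ties go to the smaller |offset|, then the negative
offset — a deterministic output contract. Unalignable k-mers seed a new
group recursively, preserving enrichment order.

Each group's position matrix accumulates every member's R value onto
the matching base at each covered position (anchor coordinates extended
by the offsets). Edge columns whose total support is below trim_frac ×
the maximum column support are trimmed iteratively from both ends
(default trim_frac = 0.25; the source protocol names no threshold).
Inner columns are never removed. When many offset k-mers populate the
top list — as in the strong planted-motif scenario — edge columns retain
roughly 35–40% of the maximum support and survive the default trim; the
planted consensus is then recovered as the contiguous core of the PWM
consensus, which is how motif recovery is scored in the tests and the
acceptance script.

## Protein features

ARM-like loci are 0-based residue centers whose 5-aa window contains
K/R at frequency strictly greater than 0.5 (≥ 3 of 5), skipping centers
within 2 residues of either terminus. Disordered regions are maximal
runs of disorder score > 0.4; putative RNA-binding domains are maximal
runs of occlusion Z < −1 (strict, following the printed cutoffs), with
a configurable minimum run length defaulting to 1 since the source
merges per-residue calls without a stated minimum. RBD-feature overlap
requires at least one shared residue (half-open intervals; ARM loci
count as width-1 intervals), with zinc-finger versus other domains
separated by a configurable label set.

## Set-overlap integration

Gene-set overlap against an explicit universe uses Fisher's exact test;
the default is one-sided (greater), matching the enrichment question and
the only panel that states its sidedness, with the two-sided variant
available. The one-sided p equals the hypergeometric upper tail, so the
`hypergeom_ge` option is the same computation. The universe defaults to
the genes actually tested in the matching knockdown (non-missing FDR),
since the source never states its universe; it is always explicit in the
API. The odds ratio is ad/bc with a 0.5 correction only when a cell is
zero. Across panels, raw p-values are reported along with
Benjamini–Hochberg adjustments, but flagging uses raw p < 0.05 to match
the source's figure convention.

Regulated-cassette counting joins binding windows to significant
skipped-exon events on the same gene: a pair supports the gene when the
gap between the window interval and any event junction coordinate is
≤ 50 bp (0 when the junction lies inside the window); genes are counted
once.

## DNA/RNA colocalization

A protein is a dual DNA/RNA binder (DRBP) when it binds strictly more
than 500 unique genes at both levels. DNA peaks are assigned to their
nearest gene by gap to the gene body; peaks more than 100 kb from any
gene are excluded from the DNA count. Signed DNA→RNA distances use
midpoints (the anchor is not defined by the source; summit-based
anchoring is a configuration away): positive when the nearest same-gene
RNA window midpoint lies transcriptionally downstream of the peak
midpoint, nearest by |distance| with ties broken downstream.

Metagene profiles bin each window midpoint into 101 integer-percent
bins, 0 at the TSS and 100 at the TTS, using the strand-oriented
fraction of gene length; 101 bins make "within 2% of transcript length"
exactly bins {0,1,2} and {98,99,100}. On the minus strand the
half-open gene end serves as the TSS-side anchor so that mirrored gene
structures give mirrored profiles exactly. Group comparisons of TSS-
and TTS-proximal density use a two-sided Mann-Whitney U per end on
per-profile summed densities (per-profile rather than per-window, the
natural unit when each profile is one dataset).

## SLAM-seq kinetics

Per gene, T>C conversion counts at chase timepoints 0/2/4/8 h are
converted to CPM against the per-library total. A replicate passes at a
timepoint when CPM > 5; a replicate is retained when it passes at all
four timepoints, and a gene is kept when ≥ 2 replicates are retained.
Retained replicates are averaged per timepoint and normalized to t = 0,
and y(t) = exp(−k t) is fitted by nonlinear least squares on the linear
scale (log-linear fitting would overweight noisy near-zero late points;
a log-linear fallback is available). The fit is seeded from the
log-linear slope. R² is computed on the normalized points; a gene passes
when R² > 0.6 and k > 0 (k ≤ 0 fails with an explicit reason).
Half-life = ln 2 / k. No plateau term is included — the source names a
plain first-order decay — but a plateau variant can be enabled.

Half-life shifts compare passed target-gene half-lives between knockdown
and control with a two-sided Mann-Whitney U, reporting the median shift
and the same test on non-targets as a specificity control (the source is
ambiguous between the two contrasts, so both are exposed).

## Ribo-STAMP EPR

EPR = edits / exonic read count per gene and sample. Genes must have
nonzero edits in all four samples (2 knockdown + 2 control — the
reading of "all four samples" adopted here) and nonzero exonic reads.
The per-gene test is a two-tailed independent t-test (pooled variance;
Welch is ill-defined at n = 2 per group) with Benjamini–Hochberg
correction, significant at FDR < 0.1. A 2-vs-2 t-test is
anti-conservative; the null simulations bound the realized false
discovery fraction at ≤ 15% rather than the nominal 10%.

## Tethering reporters

Per-well firefly/Renilla ratios are normalized to the mean ratio of the
control construct (the baseline construct is configurable; the source
does not name it, and `"control"` is the default label). A construct is
a hit when a one-tailed independent t-test against the control wells in
the stated direction gives p < 0.05 with ≥ 3 replicates per side. For
the splicing minigenes the tested quantity is an inclusion proxy,
100·firefly/(firefly + renilla) per well (the conversion the source
plots is not printed; the formula is configurable), tested separately
for upstream- and downstream-tether constructs, a ZFP being a splice hit
if either is significant. Hit decisions are invariant under global
rescaling of luminescence.

## Synthetic data: what it emulates and what it does not

Each generator draws from its own RNG stream derived from the master
seed and a stable label, so generators can be added without perturbing
each other, and a fixed seed yields byte-identical output files.

* **Annotation** — non-overlapping genes of 4–12 kb on both strands with
  1–10 exons, a long terminal exon hosting the 3'UTR (as in typical
  protein-coding genes, and necessary for the planted-3'UTR scenario to
  be identifiable: in very short exons most UTR positions fall within
  300 bp of a splice site and the splice-site classes would absorb
  them), and a 15/70/15% UTR5/CDS/UTR3 split of exonic space.
* **Binding** — per-window Bernoulli placement. The planted feature's
  in/out placement odds are the planted odds ratio times the genomic
  background odds, so the downstream 2×2 estimate is consistent by
  construction. A TSS bias of b puts mass b·0.03 on the first 3% of the
  transcript. Cut&Run peaks concentrate within 1 kb of the TSS for a
  configurable fraction.
* **Knockdown tables** — per-event-type counts are Poisson around batch
  means (defaults 100 and 1000, the order-of-magnitude contrast the
  batch model exists for); outliers inflate the mean by a planted excess
  fraction. Emitted differential tables reproduce the planted counts
  exactly under the significance thresholds.
* **SLAM** — counts are Poisson(depth · 2^(−t/hl)) with a fixed library
  total (defaults: depth 1000, library 2×10⁶, 3 replicates), a no-noise
  mode for closed-form checks, and truth flags for genes whose expected
  CPM falls at or below the filter.
* **RBNS** — uniform 20-nt RNA input pool; the pulldown plants one PWM
  draw per read at a uniform position in a planted fraction of reads.
* **EPR** — per-gene baseline edit rates are lognormal around 0.05 with
  exonic reads around 20 000 (deeply covered, well-expressed genes: with
  2 replicates per arm, the 2-vs-2 t-test only has power when counting
  noise is a few percent, and genes with low edit counts are exactly the
  ones the nonzero-edits filter removes in practice).
* **Tethering** — lognormal luminescence (CV 10%) around construct
  means; the control wells are shared by every contrast, so per-run null
  hit rates are correlated: conditional on one control draw the realized
  rate can sit well below the 5% marginal rate.
* **Proteins** — K/R-free background residues with planted solid K/R
  runs (qualifying window centers are then exactly the run positions),
  occlusion-Z dips strictly below −1 on planted RBDs, and disorder
  stretches above 0.4 on planted IDRs.

Passing these tests demonstrates estimator correctness and calibration
under the stated noise models, not robustness to real-data pathologies:
no overdispersion beyond Poisson/lognormal, no mappability or GC
structure, no overlapping genes or alternative isoforms, no correlated
replicates, and the RBNS input pool is exactly uniform.

## Numerical choices and degenerate inputs

Empty window sets, empty universes, missing controls, single-dataset
batches, sub-threshold replicate counts and zero-length genes raise
errors naming the problem. Externally studentized residuals fall back to
t = 0 when the leave-one-out variance is non-positive (all-equal
batches). Decay fits return explicit failure reasons instead of raising.
The Fisher/hypergeometric path is exact (scipy's hypergeometric
survival function), matching the enumeration oracle to 1e-12 on small
universes. Problem sizes in tests and the acceptance script (≈ 100–200
genes, 2–5 k windows, 50 k reads, 10-seed repetitions) were chosen so
each planted effect is estimated with sampling error comfortably below
the recovery tolerances.

## Known limitations

* The metagene profile bins window midpoints, not per-base coverage;
  very long windows are represented by a single bin.
* Nearest-gene assignment for DNA peaks is a linear scan per peak,
  adequate at the tens-of-thousands scale this package targets but not
  indexed for whole-genome peak atlases.
* `read_table` trusts the named schema for typing; columns outside the
  contract are carried but not validated.
* The RBNS aligner considers offsets of at most one position, following
  the protocol it implements; longer offsets would require a different
  grouping rule.
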