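# Methods

`starrmap` re-implements a genome-wide STARR-seq analysis as a tested
pipeline: activity quantification from paired input/RNA fragment libraries,
enrichment peak calling with published filters, changepoint-based strength
classification, chromatin and genomic annotation, PWM motif analysis with
exact p-values, YY1 dosage/mutagenesis, and screen-design utilities. A
synthetic-data generator provides inputs with known ground truth so every
stage can be validated quantitatively without sequencing data.

## Activity model and quantification

STARR-seq measures the enhancer capacity of a genomic fragment as the
abundance of its self-transcribed reporter RNA relative to its abundance in
the plasmid input library. Per target or window,

    activity_fc = (k_rna / N_rna) / (k_in / N_in),   activity_log2 = log2(activity_fc)

with counts normalised to reads per million (RPM). When either raw count is
zero, 0.5 is added to both counts before normalisation so log activity stays
finite; targets with fewer than 10 input fragments (`min_input_count`) are
flagged unquantifiable rather than reported. Region counting uses a ≥ 1 bp
overlap rule by default (`min_overlap_bp` exposed), verified against an
all-pairs oracle. Replicate agreement is the squared Pearson correlation of
per-500 bp-bin RPM over bins with signal in at least one replicate; reporter
(GFP/SEAP) tables are normalised to percent of a full-length reference
construct after background subtraction.

## Peak calling

The genome is scanned in 500 bp windows at 100 bp stride. Three statistical
choices matter and are deliberate:

* **Midpoint counting.** A fragment is assigned to the windows containing
  its midpoint. The assay transcribes whole inserts, so a fragment that
  clips a window edge carries no information about that window; midpoint
  assignment also makes the window-level activity estimator unbiased for
  planted enhancers (overlap counting dilutes it by ~0.7 log2 at the
  default 800 bp fragment / 500 bp window geometry). `count_mode="overlap"`
  is available.
* **Conditionally exact binomial test.** Under the null, given
  `t = k_rna + k_in`, `k_rna ~ Binomial(t, N_rna/(N_rna+N_in))`. The
  plug-in alternative (input proportion treated as known) is kept as
  `p_method="plugin"` but is anti-conservative at high depth because the
  input library has sampling noise of its own; the conditional test is
  exactly calibrated, which the enhancer-free null simulation checks
  (passing-window fraction ≤ 1e-4 at p < 1e-5).
* **Median-of-ratios composition correction.** A fixed-size RNA library is
  a composition: strong enhancers soak up sampling mass and deflate every
  raw RNA:input ratio by the library's mean enhancer weight (~2.3 log2 at
  generator defaults). Window ratios are divided by the genome-wide median
  ratio (as in RNA-seq size factors) so background sits at 1 and enhancer
  windows read out absolute activity. `normalize="none"` disables it.

Windows passing p < 1e-5 and log2 enrichment ≥ 2.5 (the published filter;
a linear-scale reading of the cutoff is selectable via `fc_scale`) on
whitelisted chromosomes are merged when overlapping or book-ended. The peak
summit is the midpoint of the best-enrichment window and the peak's
enrichment and p-value are taken from that window. Low-input windows
(< 10 input fragments) are flagged and never called.

## Strength classification

Enhancers are ranked by log2 activity and the ranked curve segmented by
changepoints in mean and variance under a Gaussian model: segment cost
`m·(log 2π + log σ̂² + 1)` (twice the NLL at the MLE, variance floored at
1e-8 to keep constant segments finite), penalty 3·log n per changepoint
(MBIC-like; the original analysis does not state its penalty), minimum
segment length 2. Three solvers share the cost: PELT (penalised exact
search, default when no changepoint budget is given), an exact dynamic
programme honouring `max_changepoints`, and greedy binary segmentation.
PELT/DP outputs equal exhaustive enumeration on all tested instances
(n ≤ 50, ≤ 3 changepoints). The activity value at the highest changepoint
becomes the lower bound for "strong", the value at the lowest changepoint
the upper bound for "weak" (the published thresholds are 4.0 and 3.1 on the
CHO data); boundary ties go to the outer class by default. Note that on
ranked (sorted) data the mean+variance cost legitimately favours many
changepoints — sorting shrinks within-segment variance — so the derived
thresholds are the extreme changepoint values, as in the original
procedure.

## Annotation

Chromatin flags use whole-peak ≥ 1 bp overlap: accessible = ATAC overlap;
H3K27ac = direct ChIP-peak overlap; H3K4me1 = overlap with the peak
extended by ±3 kb (boundary inclusive); H3K9me3 = direct overlap.
Genomic-feature assignment uses the summit with precedence
promoter_tss > tts > utr5 > utr3 > exon > intron > intergenic, promoter
window −1 kb..+100 bp and TTS window −100 bp..+1 kb (the conventional
peak-annotation defaults; both configurable), strand-oriented. The nearest
gene minimises |summit − TSS| and the signed TSS distance is positive
downstream in gene orientation. Tissue classes map "low tissue specificity"
to ubiquitous and "tissue enhanced/enriched, group enriched" to
tissue-specific; unknown genes are labelled unknown and unrecognised
categories are an error. Group-wise expression comparisons use one-way
ANOVA on log2(TPM+1) with Bonferroni-corrected pairwise t-tests.

## Motif analysis

PWMs carry per-position base probabilities; log-odds are computed in log2
units against a 0-order background after adding `0.1 × background`
pseudocount. Scores are discretised at 1e-3 log2 units and the exact null
distribution of the score is built by dynamic programming (per-position
convolution over the integer score lattice), so hit p-values are exact tail
sums — the DP equals full 4^w enumeration to < 1e-12 for w ≤ 8. Both
strands are scanned, N-containing windows are skipped, same-position
opposite-strand duplicates keep the better score, and overlapping hits of
one motif are collapsed greedily by score before counting. The bundled
motif set contains a synthetic YY1-like matrix (ATGG core, consensus
CAAGATGGCGGC) and a synthetic ETS-like matrix (GGAA core); any MEME-format
motifs can be supplied. MEME minimal files are parsed directly at printed
precision.

Backgrounds for enrichment shift the unfiltered peak coordinates +10 kb
(strand-agnostic), dropping regions past the chromosome end, overlapping a
retained peak, or with < 10 input fragments. Enrichment is
presence/absence per sequence with a one-sided Fisher's exact test,
Benjamini–Hochberg across motifs, and a fold of presence percentages
(0.5 added to each 2×2 cell when a zero occurs). YY1 dosage bins enhancers
by deduplicated hit count (0,…,4,5+), reports per-bin activity summaries,
one-way ANOVA, and the least-squares slope of activity on the capped count.

Mutagenesis replaces the four conserved core positions of each hit — where
the consensus reads ATGG — with CTCG in hit orientation (minus-strand
genomic CCAT → CGAG). The edit is positional rather than string-matched so
degenerate hits whose core deviates from ATGG are still disrupted; by
construction a CTCG-core window cannot re-pass the 1e-4 scan threshold
(maximum attainable mutant score 9.59 vs threshold 10.83 for the bundled
matrix), which makes the designed mutants re-scan clean. Candidate
selection takes the top 50 peaks (by activity) with ≥ 2 deduplicated hits,
trims to the minimal hit-covering window plus padding, and iterates
mutate/re-scan until no hit remains.

## Screen design

Tiling emits seven 500 bp tiles per peak (labels −3..−1, summit, +1..+3) at
stride 300 (200 bp overlap), summit tile `[summit−250, summit+250)`;
out-of-bounds tiles are dropped with a warning. The model-window dataset
cuts 249 bp windows at stride 100 — central window
`[summit−124, summit+125)`, the odd base placed downstream — plus three
windows per side, attaches the per-window RPM fold change, optionally adds
background windows sampled uniformly outside peaks ±1 kb, and splits
80/10/10 into train/validation/test with all windows of a peak kept in one
split (seeded). Cloning-arm assembly concatenates the fixed 5′ homology
arm, 5′ adapter, insert, 3′ adapter and 3′ homology arm, bit-exact.

## Synthetic data: what it emulates and what it does not

The generator builds a uniform-composition toy genome (three 500 kb
chromosomes named "1", "2", "scaffold_1"; the scaffold exercises the
chromosome whitelist and carries no enhancers), a non-overlapping gene
model with exon/CDS structure, and 200 planted 500 bp enhancers with log2
activities uniform on [2.6, 6.9] — the six- to 117-fold enrichment range
the analysis targets. RNA libraries are rejection-sampled from the input
fragment distribution (starts uniform, lengths Normal(800, 50) clipped to
[100, 1500]) with weight 2^activity for candidates overlapping an enhancer
by ≥ min(250 bp, half the enhancer length): whole-insert transcription is
modelled as a containment proxy, and the weight→abundance law is an
assumption validated only by self-consistency (recovery), not against
external data. Enhancers keep ≥ 2 kb separation so each called peak maps
to one planted element — the resolvability condition the recovery metrics
assume. An exact 49% of enhancers are accessible (ATAC + H3K27ac overlap,
H3K4me1 within ±3 kb, decoy peaks elsewhere), half of those placed within
±500 bp of a TSS; masked enhancers stay TSS-distal and optionally carry
weak H3K9me3. YY1 instances are embedded with count
`floor(activity quantile × 5)` (the dosage law is linear by construction;
the real data only reports a correlation), ETS instances mark accessible
enhancers, and expression/tissue tables couple nearest genes to
accessibility and strength at 90% label purity.

Passing tests on this generator demonstrates internal statistical
correctness — estimator calibration, recovery, monotonicity, oracle
equality — not performance on real sequencing data: the generator has no
GC/mappability bias, no PCR duplication, no read-level error, uniform
fragment coverage, and independent enhancers. Those are exactly the
covariates the original peak caller corrects for and that this simplified
binomial caller does not.

## Problem sizes and defaults

Default study: 3 × 500 kb genome, 200 enhancers, 1M fragments per library,
2 RNA replicates — chosen so that a window holds ~330 input fragments and
the weakest recoverable enhancers (log2 ≥ 3) are detected with ~7σ margin.
The full simulation runs in ~10 s and the acceptance script in ~20 s on one
CPU. Key defaults: window 500/stride 100, min input 10, p < 1e-5,
log2 FC ≥ 2.5, whitelist 1–10+X, strength penalty 3·log n, motif p < 1e-4,
background shift 10 kb, tiling 500/200, dataset windows 249/100 with
80/10/10 split.

## Known limitations

* The binomial caller has no covariate correction (GC, mappability) and no
  replicate-aware reproducibility analysis; replicates are pooled.
* Exact changepoint search is O(K n²); for n ≫ 10⁴ use PELT (default).
* The median-of-ratios correction assumes most windows are background; it
  would mis-scale a genome where enhancers dominate the sequence.
* Motif p-values are exact only up to the 1e-3 score discretisation, and
  the bundled PWMs are synthetic stand-ins labelled as such, not measured
  binding models.
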