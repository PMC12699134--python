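# starrmap

Genome-wide STARR-seq enhancer mapping and characterization, as a tested
Python library and CLI.

STARR-seq (self-transcribing active regulatory region sequencing) clones
random genomic fragments downstream of a core promoter so that active
enhancers transcribe themselves; enhancer activity is then the
reads-per-million fold change of a fragment's abundance in the reporter RNA
library over the plasmid input library,

    activity = log2[ (k_RNA / N_RNA) / (k_input / N_input) ].

`starrmap` implements the downstream analysis of such a screen for people
who want to map and rank enhancers from fragment-level data:

* **quantify** — fragment counting, RPM/RPKM normalisation, targeted
  activity tables, signal-to-noise against negative controls, replicate
  correlation, reporter (GFP/SEAP) percent-of-reference normalisation;
* **peaks** — a sliding-window RNA-over-input caller (500 bp / stride
  100 bp) using a conditionally exact binomial test and median-of-ratios
  composition correction, with the published filters p < 1e-5,
  log2 enrichment ≥ 2.5 and a regular-chromosome whitelist;
* **strength** — changepoint segmentation (Gaussian mean+variance cost;
  PELT / exact DP / binary segmentation) of the ranked activity curve into
  weak / intermediate / strong enhancers;
* **annotate** — ATAC/H3K27ac/H3K4me1(±3 kb)/H3K9me3 flags, summit-based
  genomic features, nearest gene and signed TSS distance, tissue-class
  mapping, group-wise expression ANOVA;
* **motifs** — PWM scanning with *exact* p-values (dynamic programming
  over the discretised null score distribution), 10 kb shifted-background
  construction, Fisher/BH motif enrichment, YY1 motif-dosage statistics and
  ATGG→CTCG mutagenesis designs;
* **design** — summit-centred 500/200 tiling, 249 bp / stride 100
  grouped-split window datasets for sequence-to-activity models, and
  synthesis-ready cloning-arm assembly;
* **synth** — a synthetic-study generator (toy genome, planted enhancers
  spanning six- to 117-fold enrichment, 800±100 bp fragment libraries,
  matching chromatin tracks, expression/tissue tables) with full ground
  truth, so every stage is testable end to end.

See `docs/methods.md` for the statistical model and design choices.

## Worked example

Simulate a default study (three 500 kb chromosomes, 200 planted enhancers,
1M fragments per library), call peaks, and check recovery against truth:

```python
import numpy as np
from starrmap import synth, peaks, annotate, motifs

study = synth.simulate_study(synth.SimConfig(seed=1), n_replicates=1)
win = peaks.scan_windows(study.input_libraries[0], study.rna_libraries[0])
called = peaks.call_peaks(win, chrom_whitelist=("1", "2"))
print(f"called {len(called)} peaks from {len(win)} windows")
```

```
called 189 peaks from 14988 windows
  peak_id chrom  start   end  summit  log2_enrichment      p_value
peak00001     1   2900  4500    3650         6.586096 0.000000e+00
peak00002     1   9200 10400    9950         3.746471 4.475115e-56
peak00003     1  14700 15700   15150         3.293046 3.833829e-22
```

Each row is a merged run of significant windows: `log2_enrichment` is the
composition-corrected activity of the best window (the estimate of the
enhancer's log2 fold change over background) and `summit` anchors tiling
and window designs. Comparing to the planted truth and continuing with
annotation and YY1 dosage:

```
recovered 189/200 planted enhancers; median |log2 error| = 0.064
accessible fraction of called peaks: 0.487
YY1 dosage: slope = 0.83 log2/motif, ANOVA p = 4.01e-113
```

The 11 missed enhancers sit below the log2 ≥ 2.5 calling threshold; the
accessible fraction reproduces the generator's 49%; and activity rises by
~0.8 log2 per planted YY1 motif, the dosage relationship the generator
encodes (motif count = activity quantile × 5).

The same pipeline runs from the shell:

```bash
starrmap run --config pipeline.yaml --outdir out/ --seed 1
starrmap simulate --outdir sim/ --seed 1
starrmap callpeaks --rna sim/rna_rep1.bed --input sim/input_rep1.bed \
    --genome-sizes sizes.tsv --out peaks.narrowPeak --chroms 1,2
```

Every run writes a resolved-config snapshot and a `manifest.json` with
seeds and output checksums; re-running with the same config is
byte-identical.

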