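# regencycle

Analysis pipeline for time-course transcriptome and chromatin profiling of
mouse liver regeneration after 70% partial hepatectomy (PH), together with
a synthetic-data generator that plants every structure the analysis is
designed to detect.

After PH, the remaining hepatocytes re-enter the cell-division cycle in
near-synchrony, making the regenerating liver a natural system for asking
how a transcriptional program is switched on genome-wide: which
transcripts change and when, whether RNA polymerase II is recruited to
promoters before it elongates through gene bodies, whether H3K4me3
"pre-marks" dormant cell-cycle genes, and where along a gene H3K36me2 is
converted to H3K36me3. The package is aimed at computational biologists
who want a tested, reusable implementation of these analyses — and, just
as importantly, a simulator with known ground truth to validate them
against.

## What it computes

**Transcript sets.** Genes with RPKM expression matrices over a post-PH
time grid (0, 1, 4, 10, 20, 28, 36, 44, 48, 60, 72 h, 1 w, 4 w; sham
controls at 1, 4, 10, 20, 48 h) are partitioned into Set 1 (never
detected), Set 2 (detected, stable) and Set 3 (detected, changing). A gene
is *changing* when a one-way F test across time points on
log2(RPKM + 1) gives a Benjamini–Hochberg adjusted *p* < 10⁻⁷ **and**
max over time points |log2 FC vs 0 h| > 0.5:

F = (SSB/(g−1)) / (SSW/(N−g)),  SSB = Σᵢ nᵢ(ȳᵢ − ȳ)², SSW = Σᵢ Σⱼ (yᵢⱼ − ȳᵢ)².

**Profile clustering.** Set 3 profiles are clustered by partitioning
around medoids (PAM, Kaufman–Rousseeuw BUILD+SWAP, implemented from
scratch) on d(a, b) = 1 − r(a, b) (Pearson correlation of log2 profiles).
Quality is scored with silhouettes sᵢ = (bᵢ − aᵢ)/max(aᵢ, bᵢ), and a
k-scan picks the silhouette-optimal number of subsets.

**Trajectories.** Sample PCA (SVD of the gene-centered log2 matrix),
average-linkage dendrograms under 1 − Pearson distance, per-hour
log2(PH/sham) ratio maps, and Spearman correlations of pathway-gene
profiles between arms.

**Chromatin.** Coverage tracks are per-base densities of the central
50 bp of sequenced fragments, normalized per million fragments, with
optional spike-in scaling (exogenous genome mixed at 19:1, reference
spike fraction 1/20). Quantification windows: Pol II promoter = TSS ±
250 bp, H3K4me3 promoter = TSS ± 500 bp, gene body = TSS + 500 bp through
poly(A) + 2 kb. Signals are log2((ChIP + ε)/(input + ε)).

**First-internal-exon anchoring.** Transcribed transcription units with
≥ 3 exons (first internal exon ≤ 2 kb) are aligned on the 3′ end of their
first internal exon; per-base H3K36me2/me3 densities from 4 kb upstream
to 1 kb downstream are assembled into matrices sorted by internal-exon
length, split at the median of an H3K36me3 score over 2 kb downstream of
the exon's 5′ end, and a change-point estimator locates the me2→me3
transition per TU.

**Simulator.** `regencycle.simulate` plants all of the above: gene
classes with seven temporal archetypes (including a 36–72 h proliferation
wave that is PH-specific, while ≤ 20 h responses are shared with sham),
circadian genes phased to Zeitgeber time and untouched by surgery,
promoter Pol II recruitment preceding gene-body elongation on induced
genes, H3K4me3 pre-marking, an H3K36me2 platform with me3 onset at the
first internal exon, and an acute-response gene class carrying Pol II
without K4/K36me3. Every run is seeded and bit-reproducible, and the
planted truth is returned for parameter-recovery testing.

## Worked example

```sh
regencycle run-all --outdir out --seed 2 --n-genes 150
```

simulates 150 genes on a 3.5 Mb chromosome and runs every stage. Key
lines of the printed summary:

```
"set_sizes": {"set1": 106, "set2": 28, "set3": 16}
"clustering": {"chosen_k": 7, "average_silhouette": 0.731, ...}
"pca_variance_ratio": [0.362, 0.256, 0.103, ...]
"exon_anchor": {"n_eligible": 37, "upper": 18, "lower": 19,
                "me2_contrast": {"upper_ratio": 0.565,
                                 "lower_ratio": 0.972,
                                 "difference": -0.407}}
"n_post_ph_genes": 4
```

Reading: 106 genes were never detected, 28 were stable and 16 changing;
the silhouette k-scan picked 7 profile subsets; the first two principal
components carry 36% + 26% of sample variance. Of 37 anchoring-eligible
TUs, the half with higher first-internal-exon H3K36me3 loses 44% of its
H3K36me2 signal downstream of the anchor (ratio 0.565) while the lower
half keeps its me2 platform (ratio 0.972) — the planted me2→me3
conversion contrast, recovered from the tracks. Individual stages are
available as `regencycle simulate | classify | cluster | trajectory`, and
all outputs are plain TSV/BED/GTF/bedGraph/Newick/JSON files.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch on seeded synthetic data
(simulation → set classification → PAM k-scan → trajectory → window
quantification → exon-anchored me2/me3 analysis) and writes the results
JSON to the given path. Stage outputs land under
`scratch/acceptance_run_seed<seed>/`.

## Layout

```
src/regencycle/
  simulate.py     synthetic annotation / expression / chromatin tracks
  annotation.py   gene models, windows, GTF/BED12 IO
  sets.py         set classification, pathway mapping, over-representation
  clustering.py   PAM, silhouettes, k-scan, heat-map ordering
  trajectory.py   PCA, dendrograms, sham-vs-PH comparisons
  chip.py         coverage tracks, window quantification, spike scaling
  anchor.py       first-internal-exon-anchored me2/me3 analysis
  pipeline.py     orchestration;  cli.py  the `regencycle` command
docs/methods.md   model assumptions, parameter choices, limitations
```
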