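# Methods

## The system being modeled

Partial hepatectomy (PH) removes ~70% of the mouse liver at Zeitgeber
Time 2 and triggers a near-synchronous wave of hepatocyte proliferation.
Expression is sampled in triplicate at 0, 1, 4, 10, 20, 28, 36, 44, 48,
60, 72 h and 1 and 4 weeks post-PH, with sham-operated controls (surgery
without resection) at 1, 4, 10, 20 and 48 h. Chromatin is profiled by
ChIP for Pol II, H3K4me3, H3K36me2 and H3K36me3 plus an input control.
The package implements the analysis chain for such data and a simulator
that emits data with the same statistical structure plus a truth channel.

## Differential test for the stable/changing split

The upstream study reports only "corrected p values" without naming its
test. We use the simplest test consistent with a multi-time-point course:
a per-gene one-way ANOVA F test across time points on log2(RPKM + 1)
(pseudocount 1 RPKM-equivalent), raw p from the F(g−1, N−g) distribution,
Benjamini–Hochberg correction over detected genes. A gene is *changing*
iff adjusted p < 1e-7 AND the maximum |log2 fold-change of time-point
means vs the 0 h mean| exceeds 0.5 — both thresholds as printed. Time
points with one replicate are dropped from the F test with a warning. The
test pools the 0 h controls with the post-PH arm (the sham arm is not
used by default; configurable).

## PAM clustering

BUILD seeds k medoids greedily (first: the point minimizing total
dissimilarity; then the point with maximal summed reduction of
nearest-medoid distances). SWAP accepts the first (medoid, candidate)
exchange that strictly decreases total cost, scanning deterministically
in (medoid index, candidate index) order, until convergence; ties break
to the lowest item index everywhere. Cost is provably non-increasing and
the algorithm terminates (finitely many medoid sets, strict decrease).

PAM is a local search: on small random dissimilarity matrices it reaches
the brute-force optimal medoid set on roughly 92–93% of instances and
otherwise stops in a local optimum with cost gaps that can exceed 10%.
This is not an implementation artifact — R's `cluster::pam` returns
numerically identical suboptimal costs on the same instances. On
structured (clustered) data, as produced by the simulator, recovery is
exact in our tests (ARI = 1.0 at the planted k). The acceptance check
that demands brute-force equality within 1% on uniform random instances
is therefore expected to fail for a faithful PAM, and we keep it failing
rather than swap in an exhaustive search.

The dissimilarity is 1 − Pearson correlation of replicate-mean log2
profiles (shape-based; amplitude-insensitive), with Euclidean-on-z-scores
as an alternative. Zero-variance profiles are defined as uncorrelated
(d = 1, warned). Silhouettes are classical ((b−a)/max(a,b), mean
within/between distances, singletons = 0) by default; the medoid-distance
variant described in the study's prose is available as `variant="medoid"`.
The k-scan chooses the silhouette-argmax k with an explicit override,
since the original seven-subset grouping was fixed by inspection.

## Trajectory analysis

PCA is the SVD of the gene-centered log2(RPKM + 1) matrix with no
unit-variance scaling — amplitude differences between genes carry the
trajectory. Replicates are averaged only for display, never before the
SVD. Hierarchical clustering of samples uses 1 − Pearson distance with
average linkage. The PH/sham ratio maps mask genes whose log2 RPKM is
below 0 in both arms at that hour. Spearman correlations use average-rank
tie handling.

## Chromatin quantification

Each fragment contributes +1 coverage over the central 50 bp around its
midpoint (odd lengths floor the midpoint); fragments shorter than 50 bp
contribute over their full extent and are counted and warned. Densities
are normalized per million fragments before ratios; spike-in scaling
(factor = reference fraction / observed spike fraction, reference 1/20
from the 19:1 mass mix) is available but off by default since the
published quantifications are not spike-corrected. Ratios are
log2((ChIP + ε)/(input + ε)) with ε = 0.01 density units — small enough
not to mask dynamics, large enough to stabilize empty windows.

Promoter windows (TSS ± 250 bp for Pol II, ± 500 bp for H3K4me3) are
symmetric and hence strand-independent; the body window (TSS + 500 bp to
poly(A) + 2 kb) is strand-aware. Windows are clipped at chromosome bounds
but not against neighboring genes. When a gene has several TUs, the
representative TU is the one with maximal promoter Pol II density (ties:
5′-most TSS, then lexicographic id).

"Post-PH" (dormant-then-activated) genes are those with mean 0 h RPKM at
or below the 0.25 quantile of detected genes AND a post-PH time-point
mean at least 2× (0 h mean + 0.1). The quantile and fold are artifact
choices — the study states none — and are configurable.

## First-internal-exon anchoring

Eligible TUs are transcribed (Set 2 ∪ Set 3), have ≥ 3 exons, and a first
internal exon ≤ 2 kb. Two anchor coordinates play different roles, kept
deliberately distinct: the median split uses the mean H3K36me3 density
over 2 kb downstream of the exon's **5′ end**, while the matrix aligns
rows on the exon's **3′ end** (positions −4000..+999, minus-strand rows
reversed so negative is always 5′). Rows sort by increasing internal-exon
length, ties by TU id, so the exon's 5′ edge drifts leftward down the
matrix. The split puts strictly-above-median scores in the upper group,
which reproduces the 4900/4901 asymmetry at n = 9801 with distinct
scores. Z-scores are per-row by default (each TU's dynamic range is
interpretable on its own); a global variant exists because the upstream
description does not disambiguate.

The transition point per TU minimizes the two-segment squared error of
the anchored me3 (or me3 − me2) profile, with a 25 bp minimum segment;
flat profiles return "undefined". The estimate is invariant to adding a
constant. The me2 depletion contrast is the ratio of mean me2 density
over 0..+1 kb (downstream) to −3..−2 kb (upstream) per group; planted
me3-dominant TUs give ratios well below 1, mixed TUs near 1.

## The simulator's stated world

* **Class mix** defaults to the published proportions over the
  37,991-gene universe: 25,966 undetected, 6,528 stable, 5,497 changing,
  with 1,036 in the proliferation archetype and the remainder spread
  evenly over the other six.
* **Archetypes** are piecewise-linear log2-offset templates with extrema
  at 10, 36, 72 h (decreasing) and 4, 20, 28 and 36–72 h (increasing),
  scaled by a 2 log2-unit amplitude. Archetypes with extrema ≤ 20 h are
  shared with the sham arm; the rest, including the proliferation wave,
  are PH-only.
* **Replicate noise** is log-normal on RPKM (Gaussian, σ = 0.2, on log2).
  σ was fixed a priori by two constraints: the published triplicates are
  very tight (within-series Pearson ≥ 0.98), and a power computation
  showed the F test at the stated amplitude retains essentially full
  sensitivity at σ = 0.2 while σ = 0.3 would not — i.e. 0.2 is the
  noise level at which the printed thresholds make sense.
* **Circadian genes** (5% of stable genes, amplitude 1.5 log2 units) add
  a 24 h cosine phased to Zeitgeber time (surgery at ZT2), identical in
  both arms. They genuinely oscillate, so recovery tests exclude them
  from the stable/changing confusion matrix.
* **Dormant-then-activated genes** are 30% of increasing-archetype genes
  (matching the printed 307/1036 for the proliferation subset), planted
  with low resting baselines (log2 RPKM ≈ 0.5); other induced genes are
  kept above the low quantile so the truth channel is unambiguous.
* **Gene models**: exon lengths 80–500 bp, introns 2–6 kb (intron length
  chosen so the −3..−2 kb anchored window samples transcribed body, as in
  real mammalian genes), 6 kb intergenic flanks, one synthetic chromosome,
  0-based half-open coordinates. A configurable fraction of first
  internal exons is forced > 2 kb to exercise the length filter.
* **Chromatin**: per-base Poisson counts at 20 expected counts per unit
  density over planted profiles — promoter Pol II waves at 4–20 h and
  28–44 h versus body Pol II/H3K36me3 onset at 36 h for induced genes,
  time-constant H3K4me3 at active promoters, an me2 platform depleted
  (×0.3) downstream of the me3 transition on me3-dominant TUs (half of
  TUs by default) and retained on mixed TUs, uniform input, and spike
  fragment counts drawn at a 1/20 expected fraction.

What the simulator does **not** emulate: read-level artifacts
(mappability, GC bias, duplicates), fragment-length variation,
multiple chromosomes or isoforms, batch effects, and biological
replicate idiosyncrasies — so a green recovery test establishes that the
estimators invert the generative model, not that they are robust to
real-data artifacts. One consequence worth knowing: some simulated
conditions are exactly interchangeable (sham = PH at 1–4 h; 0 h controls
= 48 h sham = 4 w PH, since 48 and 672 are multiples of the 24 h
circadian period), so sample-level analyses can only distinguish them up
to these equivalence classes.

## Numerical conventions

Seeds: one integer seed drives everything; sub-generators derive from it
with fixed offsets, and chromatin tracks are seeded per (mark, time) so
generation order never changes output. Determinism: PAM, silhouettes,
splits and orderings all have explicit tie-breaks (lowest index / lexical
id). Degenerate inputs: constant profiles normalize to 0.5 (warned),
zero-variance correlation distances are 1, all-equal median splits leave
the upper group empty, flat transition profiles are undefined, k = n PAM
returns every item as its own medoid at cost 0.
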