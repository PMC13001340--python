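# Methods

`hlbquant` quantifies the chromatin occupancy and mRNA output of the
*Drosophila* replication-dependent (RD) histone gene array — a single locus
carrying ~100 tandem copies of a 5,080-bp unit housed in the Histone Locus
Body (HLB) — and the cell-cycle coupling of its expression. Because the
sequencing and imaging data these analyses were designed for are not
publicly deposited, every pipeline stage is driven by a synthetic-data
generator with known ground truth; the generators are first-class, tested
code, and the calibration studies in `tests/test_acceptance.py` and
`scripts/acceptance.py` state exactly what the pipeline recovers under
those conditions.

## Collapsed-repeat reference and fragment projection

A tandem array cannot be mapped copy-resolved, so the reference is rebuilt:
the printed array interval (1-based inclusive, e.g.
chr2L:21,400,839–21,573,418, a 172,580-bp span) is excised from its
chromosome and a single consensus unit is appended as its own chromosome
(`chrHis`, 5,080 bp). The copy number is an independent parameter and is
never inferred from the excised span — the native locus is only partially
assembled, so the declared interval is shorter than `copies × unit`.

Fragments in expanded-array coordinates are projected deterministically:

* wholly inside the array → consensus offset `(pos − array_start) mod L`;
* spanning a copy–copy junction → two pieces wrapped across the consensus
  end/start (the repeat is head-to-tail, so the unit is treated as circular
  for projection; `wrap=False` drops such fragments instead);
* upstream unchanged; downstream shifted left by the expanded array span;
* straddling the array's outer boundary → dropped and counted, because no
  unambiguous collapsed location exists.

Internal coordinates are 0-based half-open; printed intervals are converted
at the I/O boundary only. Projection conserves bases exactly (minus dropped
boundary fragments) and is the identity on consensus-chromosome and
non-array-chromosome coordinates. Coordinates on the excised chromosome
itself are not re-projectable: after the downstream shift a collapsed
position can coincide numerically with the expanded array interval, so the
operation is defined from expanded coordinates only, and no pipeline path
applies it twice.

## Coverage, CPM and per-gene-copy (HGC) normalization

Coverage is binned at 2 bp by default. A bin's value is the summed per-base
fragment depth divided by the nominal bin size, so
`sum(values) × bin_size` equals total fragment bases exactly — the mass
identity the genome scan relies on. CPM is counts per million mapped
*fragments* (paired-end semantics): each value is scaled by
`1e6 / n_fragments`, where junction-wrapped pieces count once. CPM is
exactly invariant under fragment duplication because the scale factor
changes by a power of two.

HGC ("per histone gene copy", also written HCG) divides consensus-chromosome
CPM by the copy number (100) so multi-copy signal is comparable to
single-copy loci. One numerical subtlety: for roughly one double in ten
there is *no* float64 `y` with `fl(y × 100) == x`, so a divided-and-stored
track cannot reproduce CPM bit-exactly by multiplication. The HGC track
therefore retains the pre-division CPM array, and
`CoverageTrack.hgc_times_copy_number()` inverts the normalization
losslessly; the materialized divided values agree with `CPM/100` to the
last ulp. Blacklist masking is conservative: any overlap at bin resolution
masks the whole bin (NaN), and masked bins are excluded from every
downstream sum.

## Genome bin scan and gene-level summaries

The scan tiles every chromosome from coordinate 0 with non-overlapping
5,080-bp bins (the repeat-unit size), sums signal per bin (not
length-normalized), retains and flags the trailing partial bin (dropping it
would silently lose terminal genes), and ranks bins with minimum-rank ties.
The Manhattan table orders chromosomes in assembly order with the consensus
last, so the collapsed unit appears at the far right.

Gene matrices scale each gene body to 2,000 bp with 500-bp flanks and
aggregate by mean into 10-bp columns (200 body + 2 × 50 flank); the column
resolution is this package's choice, as is mean aggregation. Minus-strand
rows are reversed so all rows read TSS-left; rows sort by descending total
signal. Clustering is agglomerative with Ward linkage on Euclidean row
distances — the upstream tooling names only a cluster count (3), not a
linkage, so Ward/Euclidean is recorded here as an explicit assumption.
Cluster labels are canonicalized by descending mean row sum, making the
labelling invariant to row order.

## RNA-FISH histogram quantification

Pixel intensities of a 1.8-µm z-window (realized as `round(window/z_step)`
slices centred on the stated slice) are summed, then binned at bin size 1
over a declared per-probe range (0–699 for H3/H2a, 0–1399 for H1/CDS).
Pixels above the range are clipped into the top bin with a logged warning —
whether the original analysis clipped or discarded is unstated, so clipping
is this package's documented stance. All bins are retained.

Histogram statistics: moment (Fisher–Pearson) skewness `g1 = m3/m2^1.5`
without small-sample correction (pixel counts are ~10^5–10^6, so the
correction is negligible) and the percentile bin, defined as the smallest
bin whose cumulative pixel fraction reaches `q/100` (the verbal definition
"90% of all pixels are less than that value" fixes only the idea, not the
tie convention). Both are invariant to pixel ordering and identical whether
computed from the histogram or the raw pixel array.

Genotype comparisons use a two-sided exact Mann–Whitney U: for group sizes
≤ 8 the null is enumerated exhaustively over all C(n+m, n) assignments of
the pooled sample (valid under ties, since the enumeration conditions on
the observed values), with the two-sided p the fraction of assignments at
least as extreme as observed; larger groups fall back to the
tie-corrected normal approximation. Benjamini–Hochberg adjustment spans
exactly the probe sets submitted in one call. Log-scale mean histograms use
`log10(mean+1)` — zeros exist at high bins and the original zero-handling
is unstated.

## Cell-class statistics and ddCt

Cell classes are boolean expressions over per-cell labels, evaluated per
embryo; proportions use all counted cells (or a stated denominator class).
Group comparisons are two-tailed t tests (pooled, Welch, or paired) with BH
adjustment across the comparisons submitted together — the family boundary
is caller-controlled because no fixed boundary is defined upstream. A
zero-variance paired design is reported as p = 1 with a warning rather than
an error (degenerate but reachable on synthetic fixtures).

ddCt follows Livak: technical replicates averaged; ΔCt against the
reference gene (α-tubulin-84D in the default simulation) within each
(genotype, biological replicate); ΔΔCt against the control-genotype mean;
log2FC = −ΔΔCt, fold change = 2^−ΔΔCt. The sign convention (reduction ⇒
negative log2FC) is the standard Livak orientation. Per-replicate RNA-input
offsets cancel in ΔCt by construction, which the generator exploits to test
unbiasedness.

## Bulk area-under-the-curve model

Per-cell transcription is a piecewise-constant rate over cycle phases
(fractions summing to 1; default the condensed S-G2-M cycle of the
embryonic ventral nerve cord, d_G1 = 0, d_S = 0.4, d_G2 = 0.4, d_M = 0.2).
The per-cycle area `Σ r_p d_p` (exact closed form, verified against
quadrature to 1e-12) predicts bulk per-embryo mRNA; the genotype area ratio
gives the bulk log2FC. Two identities matter: a gene whose maximal output
drops to `f = d_S/(d_S+d_G2+d_M)` while expressing over the whole cycle has
log2FC exactly 0, and a gene with unchanged maximum and the same extension
has log2FC `log2((d_S+d_G2+d_M)/d_S)` ≈ 1.32 — one phase setting yields
both regimes simultaneously. mRNA decay defaults to 0 (an optional
first-order rate reports end-of-cycle surviving mRNA instead). The
Monte-Carlo cross-check places cells at uniform random cycle positions
(steady state, no decay) and estimates the area as the population-mean
instantaneous rate — the unique reading under which an asynchronous
population estimator converges to the closed-form area. The model is
illustrative: no claim is made of fitting measured fold changes.

## Synthetic-data generators: what they emulate, and what they do not

All randomness derives from one root seed via `numpy.random.SeedSequence`
with fixed per-stage spawn keys (`stage_rng`), so stages re-run
independently and reproduce bit-identically.

**Genomes.** Background sequence is uniform random ACGT; the expanded array
is exactly `copies` head-to-tail units. The expansion is an idealization:
the native locus is under-assembled (172,580 bp printed vs 508,000 bp
expanded), and the generator models the *true* biological array, not the
assembly gap.

**Fragments.** Start positions are drawn with per-bp weight 1 everywhere,
× enrichment inside the array, × fold inside optional off-target peaks.
Lengths are Normal(150, 30) truncated to [50, 700] — the upper bound
matching the common 700-bp paired-end alignment limit; the real libraries'
insert distribution is not described. No sequencing errors, mappability,
MAPQ or duplicate structure are modelled, so enrichment recovery here
demonstrates correctness of the normalization arithmetic, not robustness to
alignment artifacts.

**Images.** A 100 × 100 µm field (the "100 µm²" phrasing in the source
material is ambiguous between area and side length; side length is the
documented default) at 0.2 µm pixels, six 0.3-µm z-slices so the stack
spans exactly the 1.8-µm analysis window, 250 cells of radius 2.5 µm placed
on a jittered grid (an epithelium-like packing; random sequential placement
cannot reach this density). Cytoplasmic signal is an annulus between 0.5r
and r around each nucleus — whole-field histogram statistics do not require
sub-cellular realism, and no optics/PSF or 3-D nucleus morphology is
simulated. In wildtype mode only S-phase cells express, at an amplitude
around the probe's maximal intensity (defaults 450/375/615/615 for
H3/H2a/H1/CDS, following printed per-probe display maxima); in mutant mode
all S/G2/M cells express at `factor × max`, with factor 0.4 for the
reduced-output probes (= d_S/(d_S+d_G2+d_M), the equal-area construction)
and 1.0 otherwise. Amplitudes carry 10% cell-to-cell and 15% per-pixel
spread; per-slice background is Normal(5, 2) truncated so summed pixels
never exceed the declared histogram range. Passing FISH tests therefore
show that the statistics *detect the constructed effect direction*, not
that real tissue would produce these exact magnitudes.

**Ct tables.** Ct = baseline − log2(relative expression) + Normal noise,
with a shared per-(genotype, replicate) offset emulating RNA-input
variation; 3 technical × 3 biological replicates, reference gene log2FC 0
by construction.

## Problem sizes and tolerances

Calibration studies run on a 3 × 1-Mb genome carrying a 100-copy 5,080-bp
array, with 10^6 fragments per library — large enough that binomial
sampling error on the recovered enrichment is ~0.3%, far inside the 5%
acceptance band. Scan detection uses 100 seeds at enrichment 50 (rank 1
expected every time) and 100 seeds at enrichment 1, where the consensus
bin's rank-1 frequency is compared with the exact binomial 99% interval
around 1/n_bins (~1/689). Note the consensus bin aggregates ~100× more
fragments than a background bin before division, so its variance is ~100×
smaller and it essentially never attains rank 1 under the null — consistent
with the interval, which contains 0. The FISH direction study uses 20
families of 5 replicates per genotype; with complete separation the exact
5-vs-5 Mann–Whitney p is 2/252 ≈ 0.0079, which survives BH across four
probes. The acceptance script scales the seed counts down (20–30 seeds) to
keep a single run short; the full 100-seed properties live in the test
suite.

## Known limitations

* The simulator's expanded array is ideal and homogeneous; diverged copies,
  assembly gaps, and copy-number variation are out of scope.
* The projection is an idealized surrogate for alignment to the collapsed
  reference; aligner-specific end effects at the consensus boundaries are
  represented only by the wrap/no-wrap switch.
* Whole-field FISH statistics are sensitive to the expressing-pixel
  fraction; fields where bright pixels are below the percentile of interest
  make the percentile statistic insensitive (the defaults keep bright
  fractions above 10%).
* The FDR family and the clustering linkage are explicit package choices
  where the upstream description is silent.
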