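# Methods

This note documents the models, formulas, parameter choices and numerical
conventions behind `fountainscope`, and what the synthetic benchmarks do and
do not establish about real data.

## Contact-matrix model

All analyses operate on balanced, binned, intra-chromosomal Hi-C contact
matrices. In memory each chromosome is a dense symmetric float matrix with
NaN rows/columns at *bad bins* — bins that received no balancing weight.
Coordinates are 0-based half-open; distances are measured bin-center to
bin-center; trans (inter-chromosomal) pixels are never used. On disk the
single-resolution cooler layout (HDF5 groups `chroms`, `bins`, `pixels`,
`indexes`) is written and read with unit weights for good bins and NaN
weights for bad bins, so matrices survive a round trip bit-exactly;
multi-resolution files with a `resolutions/<res>` group are read as well.
Dense storage is deliberate: the package targets desk-scale matrices (a few
thousand bins per chromosome), where dense linear algebra is simpler and
faster than sparse bookkeeping.

## Expected, O/E and the loop-size estimate

The expected profile is the per-diagonal mean of unmasked pixels, per
chromosome, with no diagonals skipped by default (`ignore_diags = 0`).
Observed-over-expected (O/E) divides each pixel by the expected value at
its separation; every defined O/E diagonal then has mean 1 exactly, which
the tests assert to 1e-9.

The relative contact probability (RCP) curve pools per-separation mean
contacts genome-wide into log10-spaced bins (8 per decade). Each bin is
plotted at the *mean separation of its contributing diagonals*, not the
nominal geometric bin center; with one or two discrete diagonals per bin at
short range, the nominal center misstates the separation and puts a
spurious wiggle of ~0.2 into the derivative. The curve is normalised to sum
to 1 over the evaluated range, making it invariant to uniform count
scaling.

The derivative d log10 P / d log10 s is taken after a centered 3-bin moving
average (and smoothed once more the same way). The **average extruded loop
size** is the separation of the most prominent local maximum of this
smoothed derivative within [30 kb, 5 Mb], requiring topographic prominence
of at least 0.05; below 30 kb short-range ligation artifacts dominate the
signal and above 5 Mb compartments do. A pure power law has a flat
derivative and returns no estimate. On an analytically constructed P(s)
whose derivative is a Gaussian bump centered at 400 kb, the estimator
returns the bump position within one log-bin (a factor of 10^(1/8) ≈ 1.33);
the exact value of any estimate shifts by about one log-bin under different
binning/smoothing choices, which is the estimator's intrinsic resolution.

## 1D loop-extrusion simulator

The simulator implements the loading → bidirectional extrusion → release
cycle on a lattice of `n_bins` sites:

- **Loading.** Each extruder occupies one site at loading, drawn from
  `loading_profile` (rejection-sampled against occupancy). The profile
  mixes a uniform component with focal mass at designated fountain bases,
  modelling preferential cohesin loading at enhancer-rich sites.
- **Extrusion.** Both legs step outward `extrusion_speed` sites per time
  step. Legs cannot pass another extruder's leg (no bypass) — the cohesin
  traffic-jam rule — and cannot leave the lattice.
- **Barriers.** A barrier is (site, orientation, stall probability).
  Orientation follows the motif-points-into-the-loop convention: a `+`
  barrier stalls the leftward-moving leg arriving from its right, a `−`
  barrier the rightward-moving leg arriving from its left, so a convergent
  pair `(+ ... −)` traps a loop loaded between the two. A blocked leg
  retries every step, giving a geometric dwell with mean 1/(1−p).
- **Release.** Two independent unloading channels: `release_rate`, the
  WAPL-activity proxy that is set to 0 in WAPL-depletion presets, and a
  small `turnover_rate` (0.01/step in presets) representing
  WAPL-independent cohesin exchange (synthesis/degradation). Without any
  turnover, extruders load exactly once, jam, and the continuous loading
  flux that builds a fountain disappears — whereas acute WAPL/CTCF loss
  *extends* fountains on the hours timescale, which is the regime the
  presets model. An unloaded extruder immediately attempts to re-load, so
  occupancy stays at steady state.
- **Capture.** After a burn-in of 25% of steps (to approach steady-state
  occupancy), each bound extruder contributes one contact between its two
  leg positions (± `contact_capture_radius`) per step, and its current loop
  span |leg1 − leg2| enters the mean-extruded-loop-size statistic. Pooled
  contacts are added onto a power-law background (exponent −1, scaled to
  equal total mass) to form an analysis-ready matrix.

**Presets.** Depletion conditions map onto single parameters: `untreated`
(release 0.15/step, absorbing barriers every 30 bins with stall 1.0, one
extruder per 100 bins, 10-kb bins, 600-bin lattice, 600 steps), `wapl_off`
(release 0), `ctcf_off` (stall 0), `wapl_ctcf_off` (both), `rad21_off` (no
extruders). The parameter regime was chosen so that the three conditions
are limited by different mechanisms — untreated by release (mean lifetime
~7 steps), WAPL-off by barrier spacing, WAPL/CTCF-off by the extruder
packing limit — which reproduces the qualitative ordering of loop sizes and
fountain extents seen under acute depletion. No quantitative extrusion
rates are published for these conditions, so the presets are directional,
not calibrated: only orderings and signs of effects are asserted, never
absolute sizes.

## Synthetic contact maps

Expected counts are a product of independent factors on a power-law decay
(exponent −1 by default): an optional log-Gaussian "extruded-loop bump" in
the decay; a compartment factor (same-label pixels × f, opposite-label
pixels / f, on ±1 block labels); loop dots (3×3 pixel blocks multiplied by
a fold); and fountains (pixels with |i + j − 2c| ≤ 3 bins and separation ≤
extent multiplied by an amplitude). The upper triangle is Poisson-sampled
to a target total and mirrored, so matrices are exactly symmetric and
bit-reproducible for a fixed seed.

With the compartment factor f, the generative saddle has corner means
AA = BB = f, AB = 1/f, hence closed-form strength f⁴; the generator exposes
`amplitude_for_strength(S) = S^(1/4)`. The measured strength deviates from
f⁴ by up to ~15% because the saddle corners average the strongest 25% of
score quantiles (not pure-label pixels) and Poisson noise regresses the
score; the recovery test therefore allows ±20%.

## Compartments

The compartment score is the leading eigenvector of the Pearson correlation
matrix of the per-chromosome O/E over unmasked bins (the GENOVA-style
construction), with the per-chromosome sign chosen to correlate positively
with an orientation track (H3K4me1-like coverage, the generating labels in
synthetic work, or a previously oriented score). Chromosomes with fewer
than 20 usable bins are skipped. NaN cells remaining inside the good-bin
submatrix (zero-expected diagonals) are filled with column means before the
correlation.

Saddle plots rank scored bins into 50 equal-count quantile groups
(configurable) and average O/E per group pair genome-wide, excluding the
main diagonal. Compartment strength is (AA·BB)/AB² where AA and BB average
the extreme ⌊0.25·n⌋ quantile groups at each end (12 of 50; ties broken
toward fewer groups) and AB averages both off-corners — published
descriptions of the statistic leave open whether one or both off-corners
enter the denominator; both are used here, and the statistic is invariant
under a global sign flip either way. Separate A and B strengths (AA/AB, BB/AB) are also
reported.

## Pileups

Aggregate loop pileups (APA) average O/E windows of side 2·pad+1 bins
(pad 200 kb at 5-kb bins by default) centered on loop pixels, with anchor
midpoints snapped to containing bins. Windows crossing a matrix edge or
reaching the masked diagonal band are dropped entirely rather than
partially masked, avoiding biased centers. Enrichment is the mean of the
central 3×3 pixels (configurable); after O/E the background is 1 by
construction. Rescaled domain pileups take each domain plus equal-length
flanks and rescale the window to 99×99 (odd, so a center pixel exists) by
exact area-mean interpolation (NaN-aware overlap weighting); enrichment is
the central-third mean.

Extended loops recombine 5′ anchors of one loop with 3′ anchors of another
on the same chromosome at 1.5–3 Mb midpoint separation, deduplicated on
(chrom, bin1, bin2) at 5-kb bins. Orientation-stratified pairing labels
each region by the strand of the CTCF motifs it contains — regions with
motifs of both orientations are excluded — and classes same-chromosome
pairs as convergent (+ upstream, − downstream), tandem (equal strands) or
divergent.

## Fountain detection

**Open chromatin islands (OCIs).** Per 100-kb bin, peak scores of all
overlapping peaks are summed (a peak contributes its full score to every
bin it touches). A bin is *high* iff the centered 5-bin window sum is
strictly greater than 100 ("4 flanking bins" is read as two per side; four
per side is available via `window_flank_bins=4`). OCIs are maximal runs of
high bins of length ≤ 10 with no high bin within 1 Mb on either side. Note
a consequence of the window rule: one isolated strong peak makes its bin
and two neighbours on each side high, so the smallest attainable island is
five bins.

**Snippets and mask.** At 20-kb resolution, the snippet at center bin c is
S[a,b] = O/E(c−a, c+b), a,b ∈ 1..50 (1-Mb window): rows look upstream,
columns downstream, so fountain signal runs along a = b. The mask is the
element-wise mean of OCI snippets (conditions averaged when several are
given), binarized at the 0.8 quantile of grid values. Sensitivity: at
quantile 0.7 the mask keeps 30% of cells and admits more off-axis
background (scores shrink toward 0 but ranks are stable); at 0.9 it keeps
the innermost short-range cells and becomes more compartment-sensitive; 0.8
balances the two and is the default.

**Scores.** For a snippet S and mask M:
fountain score = mean(S inside M) − mean(S outside M);
mask correlation = Spearman correlation between S values and the M
indicator; noise score = coefficient of variation of S outside M.
Constant snippets score 0 with correlation 0. Prominence is the
topographic prominence of the *genomic fountain-score profile* at the
candidate peak, computed within a ±1 Mb window. These formulas follow the
documented intent of mask-based fountain scoring; the original tool's exact
binary behaviour is not reproduced, so call sets on real data are expected
to agree methodologically, not identically.

**Filter chain.** Candidate peaks are local maxima of the 3-bin-smoothed
merged score profile (ties leftmost). In order: (1) prominence at or above
the Li minimum-cross-entropy threshold of the candidate prominence
distribution (mean initialisation, tolerance 1e-6); (2) no bad bin within
100 kb; (3) positive mask correlation; (4) a candidate peak within ±60 kb
in each of the two replicate profiles; (5) drop candidates in the top 10%
of the noise-score distribution; (6) drop candidates in the bottom 30% of
the fountain-score distribution. The stage-5/6 cutoffs are, by default,
quantiles of the **full candidate distribution** applied to the survivors:
they act as absolute, data-calibrated thresholds, so a uniformly strong
candidate set is not decimated. The alternative reading — fractions of the
set entering each stage, removing exactly ⌊frac·n⌋ — is available as
`fraction_reference="survivors"`; under that semantics any pipeline whose
hard filters reduce the pool to the true set must discard ~37% of true
calls, which caps recall at ~0.63 regardless of data quality. The two
semantics coincide when every candidate survives the earlier stages.

**Interaction profile.** For a base bin c, profile(k) is the mean O/E over
the perpendicular diagonal through c and three flanking perpendicular
diagonals on each side: O/E(c+j−k, c+j+k), j ∈ [−3, 3], at separation
2k·binsize, over unmasked in-bounds entries. The profile's *extent* is the
largest separation still above 1.05.

## Permutation tests

Chromatin-state enrichment uses circular randomisation: base intervals are
rotated along each chromosome by an independent uniform offset with
wrap-around (intervals split at the end are kept as two pieces; counts and
total lengths are asserted preserved each permutation), N = 100 by default.
Observed overlap is measured in bp (or interval counts). Gene-label
permutation assigns genes to 100-kb fountain-base flanks by TSS position
(gene-body overlap is the documented alternative; TSS is used for
consistency with the E-P rule), permutes labels over all genes preserving
counts, and reports observed versus permuted mean/min/max per label,
separately for the in-flank and rest-of-genome sets. Empirical p-values use
the +1 correction, p = (1 + #{perm ≥ obs})/(1 + N), so N = 100 caps
resolution at ~0.01 and no multiple-testing correction beyond the raw p is
applied. E-P genes are those with a TSS within 2 kb (inclusive) of an
enhancer-promoter loop anchor, distance 0 inside the anchor.

## Benchmark scenarios and problem sizes

The fountain benchmark uses one 40-Mb chromosome (2000 bins at 20 kb) with
20 fountains (amplitude 3×, 600 kb extent) on the bin grid, a 2-Mb
checkerboard at factor 1.15, 50 loop dots at fold 3, and two replicates of
5×10⁶ Poisson counts pooled into a merged map; the mask trains on snippets
at 10 of the 20 bases. The pipeline attains precision = recall = 1.0 at
±60 kb matching (recall 0.95–1.0 across seeds). At amplitude 1.5× recall
stays ≥ 0.9 but precision drops to ~0.45: a weak fountain's score is
comparable to the perpendicular-band signal that an A-block center produces
in a checkerboard, and mask-based scoring cannot distinguish the two — on
real maps such calls would land at active-domain centers, which is exactly
where true fountains live, so the degeneracy is intrinsic to the pattern,
not an implementation artifact.

Simulator-based suites use 600-bin lattices, 10 seeds for loop-size
orderings and 3 pooled-ensemble maps for profile and pileup comparisons;
compartment suites use 1000–2000 bins at 100 kb with 2–5×10⁶ counts. These
sizes keep the full test suite and the acceptance script to a few minutes
on one CPU while leaving every assertion comfortably clear of its noise
floor.

## What the synthetic benchmarks do not show

The generator's fountains are sharp-edged, equal-amplitude and isolated;
real fountains vary continuously in strength and extent, sit in
sequence-dependent backgrounds (stripes, TAD corners) that the generator
only partially emulates (loops, checkerboard), and their replicate
structure involves library-level artifacts beyond Poisson resampling.
Passing the recovery benchmarks therefore establishes correctness of the
transforms, scores and filter logic — not that any particular published
call set (or its exact count) would be reproduced from deposited
sequencing data. Likewise the
simulator is 1D and kinetic, not a 3D polymer model: it supports
directional claims (orderings under perturbations), never absolute contact
frequencies.
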