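# Methods

## Scope and model

`senhic` analyzes binned, per-chromosome (cis-only) Hi-C contact matrices.
All coordinates are 0-based half-open; the working resolution is 40 kb, with
coarsened 200 kb views for compartment-level contact scoring. Trans
(inter-chromosomal) contacts are ignored throughout: every statistic the
package computes — compartment scores, LVS, border strength, O/E — is
defined within one chromosome, and chromosome-level results are pooled only
where stated (z-standardization of border strength, SAHF thresholding,
occupancy comparisons).

## ICE balancing

Hi-C counts are modelled as `C_ij = b_i b_j T_ij` with a symmetric truth `T`
and multiplicative per-bin biases `b`. Balancing drives all unmasked row
sums to a common value. Each of the `n_iter` iterations (default 30) is one
alternating Sinkhorn pass — rows rescaled to the mean row sum, then columns
— with the final bias symmetrized as `sqrt(u·v)` so the output stays exactly
symmetric. The alternating update converges far faster than the plain
simultaneous update (relative row-sum spread ~1e-5 after 30 passes on a
1000-bin map with log-normal SD 0.5 biases, vs ~6e-3 for the simultaneous
form), while fixed points are identical. The total count sum is restored
afterwards so normalization is a pure rebalancing. Bins in the lowest 2 % of
raw coverage (strictly below the quantile, so a perfectly uniform map masks
nothing) and zero-coverage bins are masked first; masked rows/columns are
zero in every downstream matrix.

## Observed/expected and decay

The expected contact at separation `d` is the mean over unmasked pairs on
that diagonal; O/E divides by it, so every diagonal of the output has
unmasked mean exactly 1. No smoothing is applied by default — at the depths
the package targets (tens of counts per pair) the per-diagonal mean is
stable; smoothing would only matter for very sparse maps. Pairs on
diagonals with zero expected mass are set to 0. The decay profile P(s) is
the same per-diagonal mean reported as a curve.

## Compartment scores

The per-bin score is PC1 of the Pearson correlation matrix of the O/E map
(columns restricted to unmasked, non-zero-variance bins), scaled
`eigenvector · sqrt(eigenvalue) · 100`, oriented so the track correlates
positively with gene density (gene-dense = A = positive). The ×100 scale
puts typical scores in the tens, compatible with the "< −20" SAHF
convention. A and B compartments are maximal same-sign runs of at least 5
consecutive bins; shorter runs, exact zeros and masked bins stay
unassigned. Zero scores are treated as unassigned rather than A or B.
Transition categories concatenate the sign letters of two conditions
(+,− → "AB" etc.); a missing or zero score in either condition gives NA.
Swap-antisymmetry (BA↔AB under condition exchange) is exact by
construction. BAB regions are bins that are BA between growing and
senescent maps and AB between senescent and knockdown maps.

If PC1 carries less than a configurable fraction of the variance (default
floor 5 %) a warning is emitted; there is no automatic fallback to PC2. A
uniform (structureless) matrix has constant O/E columns, which are dropped
as zero-variance, and the chromosome errors out as too short — degenerate
input is reported, not silently scored.

## SAHF detection and the threshold scale

SAHF bins are those with score strictly below a threshold. The historical
convention (−20) is the default, but the absolute score scale depends on
matrix size, depth and structure strength, so the cutoff is calibration-
dependent. For synthetic studies the package provides
`sahf_threshold_from_scores`, a parameter-free Otsu split of the
negative-score tail: it finds the two-cluster boundary minimizing
within-cluster variance, i.e. the scale-free analog of "the strongly
negative tail". On the synthetic calibration, B-compartment scores sit far
below −20, so the fixed cutoff flags heterochromatin broadly (all planted
SAHF included, precision limited to "is in a B block"), whereas the Otsu
rule preferentially keeps the long-range-boosted blocks; its recall of
planted SAHF bins is typically 0.85–0.99 depending on how much of the
chromosome the SAHF blocks occupy. Both behaviors are tested; the pipeline
exposes the choice (`sahf_auto_threshold`). Note the Otsu rule always flags
*something* — in a condition with no genuine SAHF it returns the strongest
ordinary heterochromatin — so condition comparisons, not the flag alone,
carry the biological conclusion.

## LVS scores

`lvs(i)` is the fraction of bin *i*'s cis contact mass (diagonal excluded)
on partners more than `distance_cutoff` (default 2 Mb) away, computed on
ICE-normalized counts. Values are in [0, 1] by construction; long + short
mass equals total mass exactly. Bins near chromosome ends have an excess of
long-range partners, so LVS has mild positional structure; comparisons are
therefore made between groups pooled genome-wide (medians), not between
individual bins.

## TAD border strength

For bin `b` with 13-bin flanks, `R(b)` is the sum of contacts within the
upstream flank plus within the downstream flank, divided by the sum of
contacts between the flanks. The pair convention is frozen: within-window
sums count each unordered pair once and exclude the diagonal; the between
sum covers all 13×13 ordered flank pairs. On a uniform matrix
`R = (78 + 78)/169 = 156/169`. The denominator carries an ε of
1e-6 × the genome-mean contact so perfectly insulated toy inputs do not
divide by zero. R is standardized (mean subtracted, divided by SD) over all
defined bins pooled across chromosomes ("across the genome"); if the SD is
degenerate all z are set to 0 with a warning.

Masked bins would otherwise fake insulation (a zeroed row deflates the
between sum for flanking bins). When a mask is present, each window sum is
rescaled by the ratio of the full window's expected (distance-decay) mass
to the unmasked pairs' expected mass, using the chromosome's own short-range
decay estimate. On mask-free input this reduces exactly to the plain ratio,
which is what the nested-loop oracle tests pin down.

Borders are local maxima of z (strictly greater than both neighbors;
plateaus take the leftmost bin; chromosome-edge NaNs disqualify) with
z ≥ `z_min` (default 1.0). Both the threshold and the tie-break are
config-exposed since only the score itself, not the calling rule, is
conventional. Border specificity across replicates: presence is matched
within ±1 bin; G-specific = in all growing replicates and no senescent one;
OIS-specific = in ≥ 2 senescent replicates and none of growing;
non-specific = remaining borders in ≥ 2 datasets; the rest unclassified.

## Enrichment statistics

*Hypergeometric overlap.* Upper-tail `P(X ≥ k)` computed via the log
survival function, so genome-scale overlaps with p far below float
underflow remain representable as `log10_p`. This doubles as a one-sided
Fisher exact test; gene-set (GO-style) enrichment uses the same operation
with Benjamini–Hochberg adjustment (statsmodels step-up).

*Pre-ranked GSEA.* Genes are ordered by decreasing score; the enrichment
score is the signed extreme of the weighted KS running sum (hit steps
`|score|^w / Σ|score|^w`, default w = 1; miss steps `1/(N−k)`). Because the
input is a single ranked list, the null permutes gene labels (redraws the
set's k positions uniformly), preserving set size; a phenotype-level
permutation is not available to a pre-ranked analysis. NES divides ES by
the mean |null ES| of the same sign; p counts same-sign nulls at least as
extreme with the +1 guard, so the floor is `1/(n_same_sign + 1)`. The
permutation loop is vectorized (running-sum extremes evaluated only at hit
positions), which keeps 2000-set calibrations at ~500 permutations each in
tens of seconds. Calibration on a null ranking rejects at 4–5 % for
α = 0.05.

*Distance windows.* Gene–SAHF distance is the gap between the gene-body
interval and the nearest SAHF region edge on the same chromosome (0 on
overlap; gene anchor = body edge, not TSS). Windows are half-open
`[start, end)`; sliding and cumulative sweeps are provided.
"Downregulated" means fold change strictly below 1; significance-flag
filtering is available but off by default.

*Track summaries, metagenes, contact-change ranking.* Per-category
summaries sample 500 bins without replacement (seeded; all bins with a
warning when fewer exist) and compare categories by two-sided Mann–Whitney.
Metagene profiles rescale each gene body to a fixed number of points
(strand-aware TSS→TES) with fixed-bp flanks and average within expression
deciles. Compartment contact change is the ratio of mean within-compartment
O/E between two conditions on a 200 kb grid, ranked ascending with
coordinate tie-breaks; the bottom fraction (default 10 %) is selected and
its genes exported for GSEA. Mann–Whitney uses the exact null for small
(min n ≤ 8) tie-free samples and the tie-corrected normal approximation
otherwise (scipy's branch rule, which matches this contract).

## Synthetic data generator

The generator encodes the statistical structure the analysis assumes, with
exported ground truth. Defaults (the package's study conditions): two
chromosomes × 40 Mb at 40 kb (1000 bins each — long enough for 2 Mb LVS
cutoffs and 13-bin windows, small enough for seconds-scale tests);
alternating A/B blocks with exponential lengths of mean 2 Mb (floor
600 kb); 10 % of bins switching between growing and senescent conditions at
a 2:1 BA:AB ratio in segments of 100–500 kb placed strictly inside blocks
with one-bin buffers; half of the BA segments reverting in the knockdown
condition (BAB); TADs of 320–480 kb (mean ~400 kb) tiling every block; SAHF
blocks covering ~30 % of the maximal persistent-B runs (several per
chromosome, so boosted long-range pairs exist).

Expected contacts follow
`λ(i,j) ∝ |i−j|^−α · C(i,j) · T(i,j) · S(i,j) · b_i b_j` with α = 1
(canonical P(s) ~ s⁻¹), same-compartment multiplier 1.6, same-TAD
multiplier 3, and a ×3 boost on SAHF–SAHF pairs beyond 2 Mb in senescent
conditions only; `b` is log-normal with σ = 0.5; the depth scale sets the
mean off-diagonal λ to 60 counts; observed counts are Poisson, drawn once
per unordered pair and mirrored. Expression: one gene per bin; log2 fold
changes are Normal(effect, 0.5) with +1 at BA bins, −1 at AB bins, −0.75 in
a ring 500–700 kb from SAHF edges (a modest but detectable positional
effect) and 0 elsewhere; with zero-mean noise about half of background
genes land below fold change 1, giving a realistic ~48–52 % genome-wide
downregulated control. The knockdown contrast shifts BAB-bin genes by −1.
Tracks: gene density elevated in (growing) A blocks — required by the
PCA sign rule — an H3K9me3-like track elevated on B and SAHF bins, and a
condensin-like track elevated on senescent-A and BA bins.

All randomness flows from integer seed sequences derived from the single
config seed (separate streams per stage/condition/chromosome), so outputs
are bit-reproducible across runs and platforms.

What the generator does **not** emulate: a real karyotype, trans contacts,
loop anchors/CTCF convergence, replication timing, lamina association,
copy-number or mappability structure, distance-dependent noise beyond
Poisson, and library-level artifacts. Passing recovery tests therefore
demonstrates the correctness and calibration of the algorithms under the
stated generative model, not performance on real sequencing data.

## Pipeline

Stages (simulate → normalize → compartments → transitions → sahf → tads →
enrich → report) communicate through plain-text artifacts in one output
directory, so individual stages can be rerun; a missing upstream artifact
raises an error naming the stage to run first. Configuration is a flat YAML
key-value file validated against the known keys (unknown keys and type
mismatches are rejected; analysis defaults follow the conventions above).
The report lists a SHA-256 checksum per artifact; two runs from one config
are byte-identical, which the test suite asserts. CLI exit codes: 0 ok,
2 config error, 3 data error.

## Numerical and testing notes

Problem sizes in the test suite and acceptance script: 1000-bin
chromosomes for recovery tests, 60-bin matrices for the nested-loop border
oracle (100 trials), 2000 random sets at 499 permutations for GSEA
calibration, 250-bin chromosomes for the double pipeline run. Tolerances:
ICE row-sum spread < 1e-3 (typically ~1e-5); O/E diagonal means within
1e-9; border-strength oracle agreement within 1e-10 relative; recovery
targets ≥ 0.9 precision/recall and ≥ 0.95 bin-sign accuracy at the default
generator conditions.

Known limitations: SAHF recovery by score thresholding degrades when SAHF
blocks occupy little of a chromosome (the PC1 signature scales with total
boosted mass); per-bin LVS comparisons are position-confounded near
chromosome ends; the Eq-style border score shares its 13-bin window across
TAD scales and is blind to borders within ~13 bins of a chromosome end;
the pipeline's replicate-specificity classification is exposed in the
library but the single-replicate demo pipeline does not exercise it.
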