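# Methods

This note records the models, parameter choices and numerical
conventions behind `chromoci`, and what the synthetic benchmark does and
does not establish about real data.

## Coordinates, bins, annotations

All coordinates are 0-based half-open, matching BED natively. A
`BinTable` tiles each chromosome with fixed-size bins (the last bin of a
chromosome may be short); bin indices are consecutive across
chromosomes in assembly order. Readers accept `chr1`-style or bare
`1`-style chromosome names but refuse a mixture within one run.

Isochore classes follow the GC% cutoffs L1 < 37, L2 37–41, H1 41–46,
H2 46–53, H3 > 53. The joins are ambiguous as written; we resolve them
half-open upward (GC = 37% → L2, 53% → H3), the only self-consistent
reading, and apply it identically everywhere. GC is accepted as a
fraction or percentage (auto-detected from the maximum). Window-level
class labels are assigned by largest base-pair overlap, ties broken by
lexicographic class name, zero overlap → `none`; nothing in the
literature specifies how windows straddling annotation edges should be
classed, so majority-overlap is our convention.

Overlap enrichment is log2((obs + ε)/(exp + ε)) with obs the
intersection bp, exp = query bp × feature bp / genome bp, and ε = 1 bp
to keep the value finite for disjoint or empty sets (flagged when a set
is empty). The statistic is symmetric in query and feature up to ε.

## Contact maps

A `ContactMap` stores the upper triangle (diagonal included) of the
binned contact matrix as integer COO records. Diagonal records count as
local contacts for the OCI — "both anchors within a window" includes
them. Raw counts are kept for the exact tests; depth normalization
(counts per million) is a separate, clearly marked representation so
Fisher tests never see scaled values. No matrix balancing (ICE/KR) is
applied anywhere: every statistic is built from raw-count ratios whose
margins absorb sequencing depth.

## OCI

Defaults: 200 kb windows, trans control, 20 Mb smoothing span, 20 Mb
cis-distal threshold, pseudocount ψ = 1, minimum 10 informative counts
per window.

* The index is a *log2* ratio. With a log, the per-chromosome median
  centering is a fold-scale offset and the statistic is symmetric in
  local/control; the sign convention (control over local) makes OCI
  rise where local contacts are lost. Absolute values are therefore not
  comparable to any particular published axis; directions and contrasts
  are.
* Control counts double-anchor each eligible record: a trans (or
  cis-distal) contact credits the window of *each* anchor, conserving
  genome totals.
* Windows with local + control below the minimum are masked *before*
  the chromosome median is taken; a chromosome with all windows masked
  is an error. The pseudocount and mask stabilize sparse windows; depth
  invariance of centered OCI holds in the regime counts ≫ ψ.
* Smoothing is a centered rolling mean over an odd number of windows
  (span in bp, floor-converted); chromosome ends use the partial span,
  masked windows are skipped and stay missing.
* On the desk-scale simulated genome (60 Mb chromosomes) the 20 Mb span
  covers a third of a chromosome, so planted effects bleed visibly into
  flanking windows; stratified contrasts survive this, absolute
  per-class means do not isolate the target class sharply. Real genomes
  (~10× longer chromosomes) are far from this regime.

## TAD calling and comparison

The directionality index uses a 2 Mb span; DI = sign(B−A)·χ² as defined
in the README. Calling is deliberately simpler than an HMM over DI: the
3-bin median-filtered DI places a boundary where the track crosses from
below −t to above +t, with t defaulting to half the median absolute
nonzero filtered DI per chromosome (a depth-free operating point).
Domains shorter than 3 bins are merged into their predecessor by
dropping the offending boundary, so domains tile the chromosome between
its first and last boundary. Users with externally called TADs can
supply them as BED and skip calling; all downstream comparisons only
need boundary positions.

Opening/closing classification fixes the TAD frame in the reference
(growing-like) condition. Cross-boundary counts use a flank of
min(TAD length, 2 Mb) — the cross-counting extent is not standardized,
and capping at the TAD length keeps short domains comparable. The
reported per-TAD ratio is cross/(intra+cross). Fisher's exact test on
the raw 2×2 counts needs no depth normalization and is exactly
computable; degenerate tables (a zero margin) are labeled stable with
p = 1 and flagged. The two-sided p is computed from the hypergeometric
pmf via vectorized log-gamma sums with a 1e-11 relative tie tolerance —
wide enough to absorb log-gamma rounding on exact ties (e.g. the mirror
outcome of a symmetric table), orders of magnitude below any genuine
probability gap at realistic table sizes — and the implementation is
cross-checked in the test suite both against `scipy.stats.fisher_exact`
and exhaustively against exact rational enumeration for all tables with
margins ≤ 50. Input tables are canonicalized under row/column swap and
transpose (which leave the two-sided p invariant) and cached.

Boundary conservation between two TAD sets is the fraction of one set's
edges with an edge of the other within ±1 bin; it is not symmetric and
both directions are reported.

## Interaction-change matrices

The "normalized interaction count" between feature classes is an
observed/expected ratio under uniform mixing: observed contact share of
a class pair divided by its share of eligible bin pairs. Eligibility
excludes cis pairs with bin-midpoint separation < 2 Mb (distance-decay
leakage); trans pairs have no separation and always count. Bins classed
`none` are excluded from numerator *and* denominator, so the matrix is
closed over labeled bins. The score is invariant to uniform depth
scaling, and the log2 change matrix is exactly antisymmetric under
swapping conditions. A class pair with no eligible bin pairs, or a zero
score in either condition, yields a 0 entry with a flag rather than an
infinity.

Replication-timing change z-scores each track genome-wide over jointly
non-missing windows before differencing, because the compared datasets
come from different systems and scales; with the
higher-value-is-earlier convention a positive Δz means earlier
replication in the second condition. A constant track is an error.

## OCI domains and clustering

Two states with Gaussian emissions on smoothed OCI: two states are
forced by the local(0)/distal(1) axis of the analysis; Gaussian
emissions are the minimal continuous choice. Fitting is Baum–Welch
(hmmlearn) with chromosomes and masked gaps as independent sequences,
initialized from a 2-means split, tol 1e-4, ≤ 200 iterations,
deterministic given the seed. The state with the lower mean is "local".
A fit whose means differ by < 0.1 pooled SD is flagged as collapsed.
EM log-likelihood is monotone up to float rounding (the final step can
lose ~1e-7 at convergence).

Decoding is Viterbi (implemented directly in log space, verified
exhaustively against all 2^n paths for short sequences). Conservation
of a reference segmentation in a query condition deliberately uses
*window-wise emission classification, not re-segmentation*: the
quantity is "fraction of windows within each reference domain classed
distal", bimodal at {0, 1} under perfect conservation. Classification
is forced monotone in the OCI value (a window at or beyond a state's
mean belongs to that state): with unequal state variances the raw
likelihood ratio is non-monotone and the wider Gaussian's far tail
would absorb query values lying *beyond the other state's mean* —
exactly the situation when a condition inverts the reference profile.

On the desk-scale simulation, domain segmentation uses a 600 kb
smoothing span rather than 20 Mb: the planted local/distal blocks are
1.6–8 Mb, and a rolling mean an order of magnitude wider than the
domains erases them (state accuracy drops from ≥ 0.95 to ~0.7). This is
a scale-matching choice, not a change to the OCI definition; on real
genomes the 20 Mb default stands in the same ratio to LAD-scale domains
as 600 kb does here.

Multi-condition clustering aggregates smoothed OCI to 1 Mb windows by
mean, takes complete cases, and applies agglomerative clustering with
Ward linkage on Euclidean distance, cut at k = 6 — the standard
unsupervised default; nothing in the method requires a particular
linkage. Clusters are renumbered by descending size so labels are
stable and comparable across runs; per-cluster mean GC is attached when
a GC track is supplied.

## The synthetic generator

The generator is the package's own construction (the phenomena it
emulates are measured, not modeled, in the literature); its outputs are
labeled as simulated. Per chromosome it lays out alternating GC-poor
(L1, mean GC 35%) and GC-rich (H2, 49%) blocks with per-bin Gaussian
noise (SD 0.6 points), makes each block lamina-associated with
probability 0.9 (L1) / 0.1 (H2), tiles TADs of 8–20 bins independently
of the blocks, and sets two histone-mark domains: H3K9me3 identical to
the LADs, H3K36me3 on the non-LAD blocks (an active-chromatin
counterpart; with a single mark class the mixing-normalized matrix is
identically 1 and the mark analysis would be vacuous).

Block lengths are class-specific — L1 8–16 bins, H2 22–40 bins — so
L1-LADs cover roughly a quarter of the genome. This minority status
matters beyond realism: if the target class exceeds half a chromosome,
the per-chromosome median centering sits on the target windows and the
planted OCI change cancels out of the centered track. A genome where
GC-poor LADs dominate would genuinely defeat median-centered OCI; real
genomes are not such genomes, and the default layout reflects that.

Expected intensities: cis pairs at separation s bins get
C·(s+1)^(−α)·τ^[same TAD], with α = 1 (typical contact decay), C = 1
(arbitrary; rescaled to depth) and τ = 3; trans pairs get β = 0.01,
putting ~13% of contacts in trans at these defaults. The senescent
condition multiplies within-TAD pairs of target-class TADs by
f ∈ (0, 1] and trans pairs between target-class bins by γ ≥ 1; the
ESC-like condition applies 1/f to the same TADs — the minimal mechanism
that inverts the local/distal profile of the target regions. Counts are
independent Poisson draws from intensities rescaled to 2 × 10⁶ pairs
per condition (Poisson rather than negative binomial: the simplest
count model; overdispersion is out of scope). Layout and each
condition's sampling use named substreams of the single config seed, so
every product is bit-reproducible.

The truth table plants: ΔOCI direction "+" exactly for bins in
target-class TADs when f < 1; an opening flag for target-class TADs;
and the ESC domain state "local" for bins in target TADs (the
compacted regions), "distal" elsewhere.

**What passing the benchmark shows — and what it does not.** The
simulation has clean block structure, a single decay exponent, no
compartment checkerboard, no loop peaks, no overdispersion, no
mappability or copy-number artifacts, and an all-or-none planted
effect. Recovery here demonstrates that the statistics measure what
they claim under their own model and are correctly calibrated under the
null; it does not demonstrate robustness to the full noise structure of
real Hi-C, and absolute performance numbers (sensitivities, accuracies)
will be optimistic relative to real data.

## Problem sizes and determinism

The default benchmark genome is 2 × 60 Mb at 200 kb bins (600 bins) and
2 × 10⁶ pairs per condition, chosen so a full simulate–analyze cycle
runs in under a second and the whole test suite plus acceptance script
in a few minutes on one CPU while keeping every per-window statistic
well away from its sparsity mask. Null calibration uses 10 seeds
(5 in the acceptance script); the effect grid is f ∈ {1.0, 0.7, 0.4}
at γ = 2.

All tables are written with fixed float formatting and carry `#` header
lines with the tool version, seed and resolved configuration; re-running
any stage with the same seed is byte-identical.

## Known limitations

* TAD calling is a thresholded-DI heuristic, adequate for boundary
  positions on block-structured maps; profile users should import their
  preferred caller's BED output instead.
* The OCI's absolute scale depends on the control mode and ψ; only
  contrasts (between conditions or strata) are interpretable.
* `class_interaction_score` materializes all upper-triangle bin pairs;
  fine for ≲ 5,000 bins, not for restriction-fragment resolution.
* BED round-trips are byte-stable for canonically formatted input only
  (tab-separated, no track lines preserved).
* The cis-distal control on short chromosomes (< 2× the threshold) has
  few eligible pairs near the ends; the informative-count mask handles
  this but cis-distal OCI is noisier there than trans-mode OCI.
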