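# Methods

This note documents the models, algorithms and numerical choices behind
`tangramcae`, and what its synthetic validation does and does not show.

## Cognitive-associative encoding

A tangram figure is seven labeled convex polygons — two large, one medium
and two small right isosceles triangles, a square and a parallelogram —
with disjoint interiors.  Canonical area ratios are large : medium : small
= 4 : 2 : 1, with square and parallelogram equal to the small-triangle
pair.  The encoding maps each figure to a symmetric 7 × 7 integer matrix
whose entry for a piece pair is one of six boundary relation codes:

| code | relation | geometric definition |
|---|---|---|
| 0 | no overlap | no boundary contact |
| 1 | complete line overlap | collinear edges whose shared segment equals both edges |
| 2 | partial line overlap | collinear edges sharing a positive-length segment equal to neither edge |
| 3 | line containment | the shared segment equals exactly one edge, strictly inside the other |
| 4 | point-line contact | a vertex on the interior of an edge, no shared segment |
| 5 | point overlap | coincident vertices |

Codes are nominal labels ordered by tightness of coupling; when several
relations hold at distinct contact loci for one pair, the lowest nonzero
code is reported (line contact dominates point contact).

**Tolerance.** All coincidence and collinearity predicates use a single
length tolerance, defaulting to 1e-6 × the figure's bounding-box diagonal,
which makes every decision scale-free.  Edge-pair analysis projects one
edge onto the other's support line and classifies the overlap interval;
point relations compare vertex distances directly.

**Interior-overlap validation.** Overlap is measured as the intersection
area of the tolerance-eroded polygons, with failure when it exceeds
tol × min(piece areas).  The erosion step matters: polygons that share an
edge whose floating-point coordinates differ in the final few ulps can
make an exact polygon-intersection kernel report a spurious
full-containment result.  Eroding by the tolerance removes boundary slivers
entirely and leaves genuine overlaps intact.

**Canonical axis order and canonicalization.** Matrix axes follow the fixed
order (large A, large B, medium, small A, small B, square, parallelogram).
Because the two large triangles (and the two small ones) are physically
interchangeable, the raw matrix is defined only up to the four
row/column permutations that swap the twins.  `encode` resolves this by
choosing the lexicographically smallest flattened matrix over that group,
making the encoding a well-defined function of the figure alone — this is
what makes it bit-identical under rotation, scaling and translation, since
no coordinate-dependent tie-break (such as centroid order) survives a
rotation.  On import, piece identities are recovered from shape: triangles
ranked by area, quadrilaterals split by a right-angle test, twins ordered
by lexicographic centroid.  Both mirror forms of the parallelogram are the
same identity.

## Encoding distance and embedding

The distance between two encodings is the L1 difference of the 21
upper-triangle codes, normalized by 21, minimized over the four
identical-piece permutations.  Because those permutations form a group, the
minimized distance keeps the triangle inequality (verified over random
triples in the test suite); its range is [0, 5].  Codes are treated as
nominal-ordinal small integers: L1 neither exaggerates large code
differences (as L2 would) nor ignores them (as Hamming would).

Embeddings use stress-minimizing metric MDS (SMACOF, 8 restarts, fixed
seed) with a deterministic classical (Torgerson) option.  Animacy
separability in the embedding is a pooled-variance two-sample t-test along
each axis, reporting the axis with the largest |t| (df = n − 2).

## Representation dimensions

**Animacy** is the fraction of a figure's whole-figure annotation labels
whose head noun (final token, matched raw or singularized) appears in an
editable animate lexicon of ~180 animals, people and agentive roles.

**Abstraction** is annotation diversity: Shannon entropy of the
canonicalized label distribution divided by log(label count), 0 for perfect
agreement and 1 when every annotator answers differently.

**Local feature density (LFD).** A granularity profile records the
cross-validated CART accuracy of a category task when the classifier sees
only the best s-piece submatrix of the encoding (s = 1…7), with the best
submatrix chosen on training folds by the summed single-cell Gini gains and
chance defined as the majority-class frequency.  LFD decomposes the total
discriminability hierarchically:

    local_excess  = max(acc(s=2) − chance, 0)
    global_excess = max(acc(s=7) − acc(s=2), 0)
    lfd           = local_excess / (local_excess + global_excess)

(0.5 when both are zero).  The incremental form is deliberate.  The full
matrix nests every local cell, so its raw accuracy can never fall below the
local one; subtracting chance from both (a symmetric form) would give a
purely local rule an LFD near 0.5 and could never exceed it, and would make
the local and global terms rise and fall together.  The incremental
decomposition assigns a single-connection rule an LFD of 1, a relational
rule invisible to any single cell an LFD near 0, and makes the two terms
complementary shares of a bounded total — which is what produces the
negative correlation between local and global contributions across a mixed
stimulus pool.  CART settings: Gini criterion, depth 4, 5-fold stratified
CV, fixed seeds.  The local deviation index is |lfd − median(lfd)| over the
stimulus set.

**Stimulus curation** greedily fills (animacy × abstraction-tertile ×
LFD-tertile) cells as evenly as possible after trimming extreme LFD tails
(5% quantiles by default).  The nine-group display order crosses binary
animacy with median splits of abstraction and LFD for the eight tangram
groups; group nine holds non-tangram (natural image) controls.

## Annotation matching

The 10-candidate matching task scores each candidate figure's encoding
under a multi-class SVM trained on (encoding, label) pairs and picks the
arg-max (ties to the lowest candidate index; chance 0.1).  Encodings enter
as 105 binary features (21 cells × one indicator per nonzero code) because
the codes are nominal — integer coding would impose a fake ordinal
geometry.  Part-label queries sum the per-label scores of the bag.
Kernels: linear, polynomial, RBF; the RBF kernel is expected to dominate
the linear one whenever label structure is relational (e.g. XOR-style
rules over two connections), which the tests verify.

## Synthetic data

The generators provide every input with known ground truth; all are
deterministic under fixed seeds.

**Figures.** A relation template (7 × 7 codes) is realized constructively:
pieces are placed along a spanning forest of the nonzero-code graph,
each attachment snapping a child edge or vertex to its parent per the
requested code (reversed edge orientation keeps interiors on opposite
sides; vertex attachments align the child's interior-wedge bisector with
the outward normal or the anti-bisector).  Site bookkeeping prevents two
attachments from claiming the same edge or vertex, clearance checks keep
non-adjacent pieces separated, and each figure is verified by re-encoding
before it is returned, then randomly rotated.  Cyclic contact graphs,
codes impossible for a piece pair (complete overlap without a common edge
length; containment without strictly nested lengths), and over-subscribed
pieces are flagged unsatisfiable.  The bundled template sampler draws only
satisfiable forests; a spanning tree on seven pieces (6 of 21 pairs) is
close to the 0.3 edge density used throughout.  The generator therefore
covers tree-shaped contact structures — real tangram silhouettes are
typically cyclic and more compact, so geometric coverage, not statistical
behavior, is the main gap between synthetic and real figures.

**Annotations.** Label multiplicities take the form (animate block,
inanimate block, distinct singletons).  The animate instance count is
planted exactly (round(a × n)); among the structures achieving it, the one
whose label entropy is closest to the abstraction target is selected.  The
two targets still interact at joint extremes (exact agreement forces
animacy 0 or 1; an exactly split animacy caps how low entropy can go), so
recovery is excellent but not perfect (r ≳ 0.96 for both dimensions,
abstraction RMSE ≲ 0.08 at uniform truths).

**Epochs.** Noise is rank-10 spatially mixed AR(1) (φ = 0.97) plus 10%
white sensor noise, calibrated to RMS ≈ 10 arbitrary units.  Defaults
mirror the recording conditions the pipeline targets: 61 channels, 500 Hz,
−0.5…1.0 s epochs, baseline −0.4…−0.1 s.  Each planted component is a
Gaussian temporal envelope × a fixed unit-norm random topography ×
the trial's condition value (binary columns map to ±1, continuous ones are
z-scored); per-image components give every stimulus its own topography,
optionally shaped so pattern distances follow a model RDM (classical MDS
of the RDM into a random orthonormal channel basis).  Familiarity
modulation shifts component latency and gain linearly in the presentation
index relative to the third presentation.  An optional artifact fraction
injects ±100-unit excursions to exercise the ±80 rejection rule.  What the
simulation does not emulate: eye/muscle artifacts with realistic
topographies, 1/f spectra, between-subject topography variability, or
latency jitter correlated with behavior — so passing tests demonstrate the
pipeline's statistical correctness and sensitivity, not performance on
real recordings.

**Behavior.** log RT = μ + Σ dimension effects + repetition effect + noise
(lognormal, μ = log 0.9 s, σ = 0.25).  Default planted effects (chosen once
as plausible magnitudes for this kind of speeded judgment): abstraction
+0.15 log-units per z (slower), animacy −0.08 (animals faster), LFD −0.05,
local deviation −0.05, repetition (0.12, 0.05, 0, 0, 0) across presentations
1–5 — a decay that stabilizes at the third presentation.  Responses are
consistent within subject × image (error rate 0.04 + 0.10 × abstraction);
a planted fraction of images (default 11.5%) instead emits exactly one
response transition across the five presentations.

## Preprocessing and decoding

Preprocessing applies average reference, zero-phase 0.1–40 Hz band-pass,
baseline subtraction (−400…−100 ms mean), then drops epochs exceeding ±80
units on any channel, returning a per-trial log.  Behavioral exclusions
drop RTs < 0.2 s or > 5 s, multiple key presses, and premature responses.

Time-resolved decoding uses a binary LDA with Ledoit–Wolf analytic
covariance shrinkage on the channel vector at each timepoint, stratified
k-fold CV (default 5), accuracies averaged over folds.  The shrinkage LDA
is implemented directly (verified against the equivalent
`LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")`) because the
inner loops run tens of thousands of fits on (trials × channels) blocks.
Channel weights are reported both raw and as activation patterns
(training-covariance-projected weights); the patterns are the
interpretable topographies, and they — not the raw weights — are expected
to match a planted source pattern.

Group curves are tested per timepoint with a one-sample t-test against
chance across subjects, one-sided (above chance), BH-FDR over timepoints.
One-sided is deliberate: cross-validated accuracy is biased slightly
*below* chance under the null, so a two-sided test flags meaningless
below-chance excursions.

Pairwise image decoding estimates a cross-validated accuracy for every
unordered image pair and timepoint (folds never split so that a test trial
influences training); missing pairs are imputed by row/column means and
flagged.  The resulting per-timepoint matrices are the neural RDMs: higher
decodability = greater dissimilarity.

Temporal generalization trains at each timepoint on one trial split and
tests at all timepoints on the other; with disjoint splits the full test
split is scored for each training fold, with overlapping splits only
held-out trials are.  The familiarity split defaults to presentations
{1, 2} vs {4, 5} (the middle presentation dropped, consistent with RT
stabilization from the third presentation onward); an RT-median split is
available.  Group-level TGM inference uses cluster-based sign-permutation
tests (cluster-forming p = 0.05, 500 permutations by default, seeded),
separately for above- and below-chance regions.

## RSA with time-resolved GLM

Six model RDMs predict the neural RDMs: animacy and object-level group
(same/different), abstraction and LFD (absolute score differences),
feature level (Jaccard distance between part-tag sets), connections (the
encoding distance).  Non-tangram stimuli have no encoding; their
connection entries are imputed at the maximum observed distance and
flagged.  Per subject and timepoint, the z-scored lower triangle of the
neural RDM is regressed (OLS with intercept) on the z-scored model
predictors; near-collinear designs fall back to a pseudo-inverse with a
warning.  Group inference: one-sample t-tests of the across-subject betas
against zero with a single BH-FDR correction across all model × timepoint
values — one joint family, so that under a global null the whole mask is
empty in about 95% of runs at q = 0.05.  Model space is summarized by
classical MDS of (1 − Pearson r) distances between model RDM vectors;
stimulus embeddings use t-SNE (or metric MDS) on a mean neural RDM with a
trustworthiness score.

## Behavioral statistics

Normalized RT is the within-subject z of log RT (plain z available).  All
group statistics operate on subject-level means — the subject is the unit
of analysis.  The four dimension contrasts (abstraction, animacy, LFD,
local deviation) use Wilcoxon signed-rank tests on paired per-subject
means with BH-FDR across the family; signed-rank rather than rank-sum
everywhere because per-subject normalization makes the two group means of
any within-subject split anti-correlated, which grossly inflates the
type-I error of an unpaired test.  The repetition analysis reports
per-presentation means, adjacent-pair signed-rank tests with FDR, and the
trial-level Pearson correlation between presentation index and normalized
RT.  Change-of-mind detection flags a subject × image pair when its
ordered response sequence contains exactly one animal/non-animal
transition (multi-transition sequences are treated as unstable and not
flagged); the image-level expected count is the mean over subjects of
per-subject flagged-image counts (fractional counts allowed), divided by
the number of analyzable tangram images.

## Problem sizes used in validation

The test suite and the acceptance script run the full pipeline at sizes
chosen to give stable statistics on a single core: 10–12 images × 4–5
presentations per synthetic subject, 10–12 channels at 100 Hz with 2–4×
temporal decimation for decoding analyses; 12 subjects for recovery and
temporal-generalization analyses, 24 subjects × 100 runs for null
calibration of the decoding FDR mask; 85 stimuli for RSA-GLM recovery and
75 images × 24 subjects for the behavioral battery; 100–200 figures for
geometry, invariance and dimension-recovery checks.  Generator defaults
remain at the full recording conditions (61 channels, 500 Hz, 85 images ×
5 presentations).

## Known limitations

- The figure generator realizes forest-shaped contact graphs only; cyclic
  templates are flagged rather than solved (a constraint solver could
  close this gap).
- Animacy/abstraction planting is exact only away from the structural
  extremes of the label distribution (see above).
- The decoding stack assumes binary contrasts for weight/pattern reporting
  and temporal generalization; multi-class contrasts fall back to a
  standard multi-class LDA without weight output.
- The FDR-mask calibrations control the family-wise rate at the nominal
  q = 0.05 under the global null, so ~5 runs in 100 are expected to show
  at least one significant point; observed empty-mask rates fluctuate
  binomially around 95%.
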