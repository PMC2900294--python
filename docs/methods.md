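# Methods

## Model

`nucpattern` scores the hypothesis that a genomic position is a
nucleosome dyad using only the W bp of sequence centred there
(default W = 301, i.e. the ~147-bp core plus ~75 bp of linker on either
side). The model has two learned parts:

1. **Position-specific k-mer patterns.** For each reverse-complement
   k-mer class (44 classes for k ≤ 3) the pattern P_m is the average over
   dyad-aligned training windows of the numerical match representation of
   m — a length-W vector with a 1 added at the start offset (leftmost
   base) of every exact, possibly overlapping occurrence — standardized
   to mean 0, variance 1. Each window contributes the representation of
   its forward sequence *and* of its reverse complement, each read in its
   own 5′→3′ frame. This makes the mirror identity
   P_{m'}(x) = P_m(−x−(k−1)) (m' = revcomp(m)) hold exactly, and makes
   patterns of self-reverse-complementary dinucleotides symmetric about
   the dyad by construction.

2. **Linear SVM weights.** Each window yields, per class, a correlation
   against P_m, a correlation against the dyad-axis reflection of P_m
   (profiles occasionally occur direction-flipped), and the two-strand
   occurrence count of m. The 3 × 44 features are standardized per column
   (training-set statistics) and weighted by a linear soft-margin SVM
   (hinge loss, L2 penalty) trained on dyad windows (+1) versus the
   windows L = 110 bp on either side of each dyad (−1).

### Strand conventions (a deliberate asymmetry)

Two coordinate conventions coexist, each chosen to make an exact
invariant hold:

* **Learning** keeps each strand's representation in its own 5′→3′
  frame. This yields the exact mirror identity above.
* **Correlation** maps the bottom-strand match vector back onto the
  forward coordinate axis (i.e. reverses it) before standardizing and
  dotting with the pattern. Each of the two terms is then a Pearson
  coefficient (the dot product is divided by W), bounding each
  correlation feature by |ρ| ≤ 2, and the strand-flip identity
  ρ(revcomp(S), P) = ρ(S, reflect(P)) is exact for every k: reverse
  complementing a window swaps corr_fwd ↔ corr_refl within every class
  and leaves counts unchanged.

  Had the correlation instead kept both strands in their own frames, it
  would be algebraically *invariant* under strand flip (the two terms
  simply exchange), and the forward/reflected features would not swap.
  Both conventions use the same information; the mapped-back form was
  chosen because it gives the feature map a clean, testable symmetry.

* **Variant assignment** uses a forward-strand-only correlation. The
  two-strand correlation is invariant under complementary swaps of the
  pattern assignment — the four nucleotide-permuted variants (AGCT,
  ACGT, TGCA, TCGA, named for the 5′→3′ order of the per-nucleotide
  maxima) differ exactly by A↔T and C↔G swaps, so a two-strand score
  cannot separate them. Single-strand correlation can, at the cost that
  a sequence and its reverse complement are assigned complementary
  variants — which is the intended behaviour for directional analysis.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| W (pattern width) | 301 | bp | core + linker extent of each pattern; odd |
| k_max | 3 | — | longest k-mer; 44 classes, 132 features |
| L (negative distance) | 110 | bp | linker offset of negative examples |
| C | 1.0 | — | SVM cost, defined against the **average** hinge loss |
| solver tolerance | 1e-4 | — | LinearSVC tol; seed fixed and logged |
| smoothing window | 11 | bp | centred moving average for score traces |
| call window | 141 | bp | local-maximum exclusion window of the dyad caller |
| artifact interpolation | off; ±80, 30 bp wide | bp | nuclease cut-site bump removal |
| significance span | 151 | bp | PSFM width for the amplitude statistic |
| significance jitter | 1000 | bp | null displacement range |
| n_sets | 1000 | — | null sets (desk scale; configurable) |

Defining C against the average hinge loss (LinearSVC receives C/n) makes
the fitted discriminant invariant to duplicating the training set; with
the sum form the same C would effectively double.

## Dyad calling from reads

Each mapped read becomes a triangle of height 1 on the genomic axis —
rising from 0 at the read start to 1 at the midpoint and back to 0 at the
last base; even-length reads put the apex at the left of the two central
positions. Triangles are summed into a trace and every position that is
the leftmost maximum of its centred 141-nt window (and has positive
trace) is called a dyad; confidence is the number of read intervals
containing the call. Calls are therefore at least 71 bp apart.
`top_fraction` takes the highest-confidence ⌈f·n⌉ calls with a
deterministic tie-break, supporting the successive-halving analyses that
grade dyad sets by positioning stringency.

## Significance null

The pattern-amplitude statistic is Δ = max − min of each nucleotide's
trace across the 151-bp PSFM of dyad-centred windows. The null draws
n_sets random sets, each the size of the dyad set, displacing every dyad
uniformly within ±1000 bp, and recomputes Δ. The reported p-value is the
add-one estimator (1 + #{Δ_null ≥ Δ_obs})/(1 + n_sets), so its floor is
1/(1+n_sets) and a constant PSFM gives p = 1 exactly. A separate,
clearly-labelled *extrapolation* fits an exponential to the null's upper
tail and evaluates its survival function at Δ_obs; the functional form is
an assumption, not a measurement, and it is never mixed into the
empirical p.

## Synthetic data: what it emulates, and what it does not

The generator plants, around each dyad of a lattice, per-offset
nucleotide probabilities from a reverse-complement-symmetric core
profile: A ramps down 5′→3′ with a trough at +40 bp, T mirrors it, G has
a Gaussian bump 40 bp 5′ of the dyad and C the mirror bump 3′, on an
i.i.d. background of GC fraction 0.46. Chosen once as defaults: profile
width 147 bp (the core), ramp amplitude 0.08, bump amplitude 0.12
(sd 28 bp), fixed 165-bp spacing, effect size 1.0 — a strong, clean
oscillation of the canonical shape. Reads are ~N(156, 10) bp (truncated
at 100) with midpoints jittered N(0, 5) around the dyad at depth 20.
An optional 10-bp sinusoid on the G/C components (default amplitude 0)
and a geometric spacing mode (gap = profile width + geometric excess,
mean 165) are available; `jitter_positions` emulates the position error
of experimental dyad estimation. Columns of the profile always sum to 1
and all randomness flows from the single mandatory seed, so fixtures are
byte-identical across runs.

What the generator does **not** emulate: mappability and coverage bias,
nuclease sequence preference at cut sites (the artifact-interpolation
code is exercised on synthetic bumps instead), repeat families,
heterogeneous nucleosome classes, and linker-length variation beyond the
geometric mode. Passing tests on this generator demonstrate that the
estimators recover what was planted under the model's own assumptions —
not that real chromatin satisfies those assumptions.

## Numerical choices and degenerate inputs

* Windows overrunning a contig or containing N are skipped, never padded;
  in training-set assembly a dropped window does not drop its mates.
* A zero-variance match vector contributes 0 to the correlation (the
  count feature carries the "no occurrences" information); a zero-variance
  *pattern* ("degenerate pattern") is an error.
* Score-trace smoothing is a centred moving average whose denominator
  counts only finite values, so contig edges are not dragged toward 0.
* ROC curves use trapezoidal area with diagonal tie segments, so AUC
  equals the Mann–Whitney statistic; "AUC = 0.5 for identical score sets"
  holds to float rounding (~1e-16).
* Dyad-caller plateau ties resolve to the leftmost position; `top_fraction`
  breaks confidence ties by (chrom, pos).
* Duplicate dyad-table rows keep the maximum confidence with a warning.

## Problem sizes used by the test suite and acceptance script

Pattern recovery uses 10,000 planted windows (mono-pattern correlation
with the planted profile ≥ 0.95; measured ≈ 0.997). Cross-validation uses
4 × 600 dyads at W = 301, k ≤ 3, L = 110 (composite AUC ≈ 0.93–0.94, and
exactly 0.5 at L = 0). The AUC(L) sweep uses geometric spacing and 25-bp
dyad-position noise, where discrimination rises from 0.5 at L = 0, peaks
in the mid-linker range, and collapses at L = repeat length. The caller
check uses depth 20, jitter sd 5 (recovery ≈ 100% within ±5 bp). The
significance null uses 20 runs × 200 sets under a null genome (median p
≈ 0.5) and 1000 sets under a planted oscillation (p at its 1/1001 floor).
Spacing uses 10,000 Bernoulli(1/165) gaps against the geometric pmf.

## Known limitations

* With the planted profile exactly as wide as the scoring window is
  short (147 bp), the score trace's mean peak shifts a few bp off the
  dyad (an edge effect of truncating the asymmetric ramp); at W = 301
  the peak is exact. Anchored-profile analyses should use the full-width
  model.
* The genome-scale figures reported for real human and yeast datasets
  (AUCs ≈ 0.89–0.93) require those datasets and are out of reach of the
  synthetic conditions here; the suite verifies the machinery and its
  invariants, not those numbers.
* The dyad caller addresses fully sequenced reads only; strand-offset
  short-tag (ChIP-seq) dyad estimation is accepted as an external input
  table rather than reimplemented.
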