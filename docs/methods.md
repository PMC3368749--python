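# Methods

## Reaction model

An entry is a four-level EC code (class 1–6 from the first field; partial
codes like `1.1.1.-` are accepted), a species list (name, Hill formula,
substrate/product role), the overall bond-change multiset, and an ordered
mechanism of per-step bond-change multisets.  Bond-change tokens
`X.Y_a.b` are canonicalized with the element pair alphabetized; orders
are integers in {0,1,2,3} (aromatic/partial orders are out of scope) and
a = b is rejected.  The stored direction is treated as canonical — no
direction inference is attempted.  Entry validity requires that the
signed composition of the mechanism steps equals the overall change set:
each token is interpreted as destroying one (X,Y) bond state of order *a*
and creating one of order *b*, and the summed state tallies of the steps
must match those of the overall transformation.  This formulation handles
transient bonds (formation cancelled by later cleavage) and order-change
chains (1→2 followed by 2→1) uniformly.

Reversal swaps species roles, maps every token `X.Y_a.b` to `X.Y_b.a`,
and reverses the step order while inverting each step; it is an
involution and preserves validity.

Species identity flags (water/hydroxide, NAD(P)(H)/FAD(H2) redox
cofactors, O2, ATP, ADP/AMP) come from a fixed name registry because the
features that consume them are defined on species identity, not
structure.  Molecular weights use IUPAC standard atomic masses.

## Descriptor sets

*Overall* and *composite* bond-change matrices use the sorted union of
tokens over the input entries as columns (or a caller-fixed column list,
used when projecting test entries onto a training feature space).

The *human designed* registry ships 28 features.  Four are the
documented engineered descriptors — `f:X-H` (bonds to hydrogen formed),
`dv:C` (total change in bond orders to carbon, counting C.C tokens twice
since both atoms are carbon), `water.OH-.su`, and `Mod_Diff`
(absolute weight difference between the largest substrate and largest
product; the absolute value is used because the sign depends on the
arbitrary annotation direction while the design goal — 0.000 for
isomerisations — is sign-free).  The rest are analogues built to the
same design intent: cleaved-to-hydrogen total, `dv:` for N/O/P/S,
formed/cleaved totals for the C-C, C-N, C-O, C-S and P-O pairs, flags for
redox-cofactor involvement, O2 as substrate, ATP-substrate-with-ADP/AMP-
product, and isomeric single-substrate/single-product pairs (equal
parsed formulas), plus substrate/product/species counts, the net
bond-order change and the total bond-change count.  The exact published
engineered list is not reproduced here; the registry is configurable so
a curated list can be swapped in.

Scaling is the z-transform with population (ddof 0) standard deviation;
constant columns map to 0 and are retained so matrix shapes are stable
across folds.  Test matrices are always transformed with parameters
fitted on training rows only.

## Similarity measures

The count-vector Tanimoto (min-sum over max-sum) is used rather than the
binary form because the descriptors are occurrence counts; it reduces to
binary Tanimoto on 0/1 vectors.  Conventions for degenerate inputs
(which arise only in synthetic edge tests): T(∅,∅) = 1, T(∅,x) = 0.
Overall reaction similarity is computed in the stored direction only.

Mechanism similarity aligns step sequences with global Needleman–Wunsch:
match score = step Tanimoto, linear gap penalty (default 0, a knob, not
a claim about the original alignment protocol), score normalised by the
longer mechanism's length so self-similarity is 1 and values stay in
[0,1] for any non-negative penalty (negative optimal scores, possible
only with a positive penalty and unequal lengths, are clamped to 0).
The similarity is computed as stored and with one entry reversed, taking
the maximum, which makes it invariant to annotation direction.  The
implementation is verified against an exhaustive enumeration of monotone
step matchings for mechanisms up to four steps.

Similarity matrices are rows = entries × columns = reference entries;
kNN and the other learners consume them as plain coordinates in
reference space, with no nearest-similarity special-casing.

## Benchmark protocol

Folds are plain random partitions with sizes differing by at most one
(stratification exists as an option but is off by default).  For each
fold: similarity matrices first have the held-out entries' reference
columns deleted; count/engineered matrices are z-scaled on the training
fold; hyperparameters are chosen by 5-fold internal cross-validated
accuracy over the grid (ties broken by grid order; a single-point grid
skips the search); the model is trained and the held-out fold predicted.
Pooled confusion counts give accuracy and R_K (the pooled convention is
used; with near-equal folds it is practically indistinguishable from
fold-averaging).  The internal tuning step reuses the outer training
fold's scaling rather than re-fitting per inner fold — a simplification
that touches only hyperparameter selection, never the outer train/test
boundary.  Per-training-fold correct counts feed the permutation test.
Similarity matrices are not re-scaled (their values are already in
[0,1]); an override flag exists.

Default grids are fixed-step: C ∈ {0.25,1,4,16,64,256}, RBF width σ ∈
{2⁻⁶,2⁻⁴,2⁻²,1,4} (mapped to sklearn's γ = 1/(2σ²)), polynomial scale ∈
{0.01,0.1,1} and degree ∈ {2,3} with the kernlab-style kernel
(scale·⟨x,y⟩+1)^degree, k ∈ {1,3,5,7,9,11}, and Random Forest mtry ∈
{⌊√M/2⌋, ⌈√M⌉, 2⌈√M⌉} with 500 trees.  Multi-class SVM uses one-vs-one
voting.  kNN uses Euclidean distance on the (scaled) features with vote
ties resolved by the nearest tied neighbour's class — deterministic and
local.  Random Forest tie-breaking is the library's seeded behaviour;
every stochastic step takes an explicit seed and results record it.

Out-of-bag accuracy is computed from one forest grown on the full
matrix.  It is an internal training measure: for similarity sets it does
not reflect the column deletions that the cross-validated results apply.

The external split scans candidate entries in order and moves any entry
repeating an already kept candidate's first-three-level EC code into the
training set (an optional flag also deduplicates against the base
training set; within-candidate deduplication is the default, matching
the arithmetic of the 60 → 43 + 17 worked example).  External validation
builds all descriptors from the training set (similarity columns = all
training entries, token universe and scaling distributions from
training) and predicts the held-out candidates.

## Evaluation

Accuracy is trace/total of the 6×6 confusion matrix; per-class accuracy
is class recall, with classes absent from the truth reported as missing
rather than 0.  R_K follows the K-category correlation formula and
returns 0 when a denominator factor vanishes; it equals the binary
Matthews coefficient on 2×2 tables (cross-checked against an independent
implementation in the tests).

The permutation test enumerates all 2^F sign assignments of the per-fold
differences (F ≤ 20).  The default criterion is two-sided,
n = #{|D_p| ≥ |D₀|}: this is the reading under which n ≥ 2 holds for any
D₀ ≠ 0, because D₀ and −D₀ always occur among the assignments; equality
counts toward n so zero-difference folds never shrink it.  A one-sided
option (D_p ≥ D₀) is retained.  The 5% level is the reporting threshold
for calling two classifiers different.

## Synthetic data generator

The generator emulates the statistical structure of a curated mechanism
corpus, not its actual chemistry.  Defaults: 320 entries with class
priors (84, 63, 73, 49, 30, 21)/320 — the ligase count is the remainder,
not an observed figure; signature strength 0.9 (each class-signature
token independently present); Poisson(1) extra tokens per entry drawn
from a fixed alphabet over {C,H,N,O,P,S} with transitions 0↔1, 1→2, 2→1;
mechanisms of 2–5 steps with 1–3 transient bond pairs; heterogeneity
h = 0.8.

Class recipes: oxidoreductases carry C-H cleavage, O-H formation and a
C-C order change, with NAD(H) and NADP(H) substrate/product pairs at
rates 10/84 and 14/84; transferases have no signature tokens (noise
only), modelling a class without clear chemical patterns; hydrolases
always include a water substrate and carry the amide-hydrolysis pattern
(C-N cleavage with C-O and N-H formation); lyases carry C-C cleavage and
C-H formation; isomerases have exactly one substrate and one product
with identical formulas (weight difference 0) and O-H/C-H signature
tokens; ligases always carry both P-O formation and P-O cleavage and an
ATP substrate with an ADP or AMP product.  An optional flag produces one
near-isomer isomerase (product one protonation state off) for negative
testing of the isomer features.

Mechanisms are built by distributing each overall token occurrence over
a random step and inserting transient formation/cleavage pairs at
ordered step positions, so step composition always reconstructs the
overall change exactly.  With probability 1−h the entry uses its class's
fixed mechanism template (step count + transient bond identities,
distinct across classes); otherwise steps and transients are drawn from
a shared pool whose bond types overlap the class signatures — which is
what degrades the composite and alignment-based descriptors as h grows
while leaving the overall descriptors untouched.  Isomerase mechanisms
always come from the shared pool, reflecting a class united only by its
substrate and product being isomers; consequently mechanistic similarity
predicts class 5 at chance while overall similarity recovers it.

What passing tests on this generator do **not** show: real curated
corpora have correlated annotation conventions, reversed-direction and
stoichiometrically irregular entries, and far richer token diversity;
synthetic separability is higher than real (cross-validation accuracies
here reach the 0.9s, versus 0.57–0.91 on the curated data), so absolute
accuracies are not comparable — only the protocol behaviour and the
relative ordering of descriptor sets are.

## Problem sizes in the test suite

The suite exercises the headline contrast at n = 120 entries, 10 folds,
a single-point Random Forest grid (√M features, 150 trees) and ten seeds
per heterogeneity level, which reproduces the overall-vs-mechanistic gap
(≈ +0.15 at h = 1, ≈ 0 at h = 0) with a sign test well under the 5%
level while keeping the whole suite fast.  The acceptance script's
quantities (permutation floor, external split sizes) are exact and run
in seconds.
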