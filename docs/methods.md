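# Methods

`tsnet` classifies patients from short clinical gene-expression time
courses (tens of patients, tens of genes, 5–7 time points, two response
classes) by moving each patient through four representations: continuous
expression → discrete gene states → maximal temporal biclusters →
a network-weighted bicluster profile, on which a similarity-kernel
classifier operates.  This note records the model, its assumptions, the
tunable parameters, and the design decisions taken where the design was
genuinely open.

## Preprocessing

Normalization precedes imputation.  The default, `zscore_gene`,
standardizes each gene over all its present values across patients and
time points; the mixture-emission initialization pools values of all
genes into shared bins, which presumes comparable scales.
`zscore_patient_gene` (per series over time) and `none` are available.
Constant series map to all-zero rather than dividing by zero.

Missing entries (skipped clinic visits, failed measurements) are filled
with a weighted mean of the three present values of the same (patient,
gene) series closest in time index, weights `1/|t − t_k|`, so the
closest observations dominate.  Neighbors are taken symmetrically in
time (past and future); distance ties go to the earlier time point, so
imputation is deterministic.  A fill value is a convex combination of
its neighbors, and present values are never altered.

## Gene-state inference (mixture-emission HMM)

Each (patient, gene) series is modeled as an observation sequence of a
shared hidden Markov model with `Q` qualitative states.  State `j`
emits through a Gaussian mixture with one component per gene
(`n` components), so gene-specific location and spread are absorbed in
the emission model while the chain captures persistence of expression
levels across contiguous time points.

*Initialization.*  `pi`, rows of `A`, and rows of the mixture weights
`w` start uniform.  All pooled values are sorted and split into `Q`
equal-count bins (remainder spread over the lowest bins); `mu[j,i]` and
`sigma[j,i]` are the mean and sd of gene `i`'s values in bin `j`, with
a fallback to the bin's all-gene statistics when a gene has fewer than
two values in a bin.

*Fitting.*  Baum–Welch over all sequences pooled, with scaled
forward–backward; component responsibilities update `w`, `mu`,
`sigma`.  Component–gene pairing is fixed (component `i` belongs to
gene `i`); only the parameters move.  Training stops when the relative
log-likelihood improvement falls below `em_tol` (default `1e-4`) or at
`em_max_iter` (default 100).  Standard deviations are floored at
`sigma_floor_frac` (default `1e-3`) of the pooled value sd.  After
fitting, states are relabeled in increasing order of emission mean
`sum_i w[j,i] mu[j,i]`, so state 1 is always the lowest expression
level and decoded vocabularies are comparable across runs and folds.
Decoding is Viterbi in log space with ties resolved toward the lower
state index.

*Scope.*  One model per dataset (or per training fold), fitted on all
(patient, gene) sequences pooled.  Cross-patient bicluster comparison
requires a shared state vocabulary, which a per-patient model cannot
give; a per-patient variant remains available behind
`per_patient_model` for exploration.  `Q` defaults to 3
(low / intermediate / high expression).

*Known limitation.*  With overlapping emission distributions the EM can
settle in a local optimum in which a component of one state parks at
another state's level, merging two states for a subset of genes; this
is visible as occasional 10–15 % decoded-state error at noise levels
where the average error is a few percent.  The equal-count-bin
initialization makes this rare but cannot exclude it.

*Baselines.*  Threshold discretizers — average, mid-range, max-X%max,
top-X%, equal-frequency partition — computed per patient within a
scope (whole matrix / per gene / per time point) are provided for
comparison.

## Temporal biclustering

A bicluster is a gene subset `G` and a contiguous window `T` of time
points over which every member follows the identical state profile `S`,
and which is maximal: `G` contains every matching gene, and the window
extends neither left nor right without losing a member.  States are
first time-stamped — state `s` at time `t` becomes the token `(t, s)`
(displayed as `t*10+s` while both are single digits) — so equal states
at different times never compare equal and windows are automatically
contiguous.

Extraction builds all `n·T` suffixes of the token sequences, sorts them
with an MSD radix sort (the leading time digit groups suffixes by start
time; within a group only state digits are bucketed), and computes
longest-common-prefix lengths between adjacent sorted suffixes.  Within
one start time, the maximal runs of the LCP array (its LCP-interval
tree) each yield exactly one candidate: the run's genes with window
length equal to the run's minimum internal LCP.  That choice of length
enforces right-maximality; a candidate whose genes all agree at the
time point before the window is discarded as extensible left.  Tokens
are kept as pairs internally, so `T ≥ 10` or `Q ≥ 10` cannot collide.

A brute-force window-enumeration oracle with the same contract verifies
the suffix machinery on hundreds of random instances; equivalence is
exact (as sets).  Defaults `ml = 2` (minimum window) and `mo = 2`
(minimum genes).

## Network weighting

Genes co-expressed by chance are less interesting than genes that also
interact.  With `N` network genes, for each member gene `i` of a
bicluster let `M` be the other members present in the network
(`m = |M|`), `d_i` the degree of `i`, and `k` the number of edges from
`i` into `M`.  The association is the upper tail
`P(X ≥ k), X ~ Hypergeometric(N−1, m, d_i)` — the probability of
observing at least this many links if `i`'s partners were drawn at
random.  `k = 0` (including genes absent from or isolated in the
network) gives exactly 1.  The bicluster's raw weight aggregates
`1 − p` over members; the default aggregator is the mean, with
`1 − geometric mean(p)` and `1 − min(p)` available.  Per patient, raw
weights are normalized to sum to one (uniform if all are zero).
Sum-normalization rather than max-normalization makes the similarity
identity property below hold by construction.

## Patient similarity (PPISim)

Two biclusters are compared with the Jaccard index over their cells:
`|B_i ∩ B_j| = |G_i ∩ G_j| × |J_i ∩ J_j|`, where a time point counts
toward `|J_i ∩ J_j|` only if it lies in both windows *and* both
profiles carry the same state there; `|B| = |G| × |J|`.

Patient similarity is the symmetrized weighted best-match

    PPISim(P1, P2) = 1/2 [ Σ_i w1_i max_j Sim(B1_i, B2_j)
                         + Σ_j w2_j max_i Sim(B1_i, B2_j) ],

which satisfies `PPISim(A, A) = 1` and symmetry — the two properties
the kernel-based classifier relies on.  A plain double sum
`Σ_i Σ_j w1_i w2_j Sim` is available (`sim_aggregation: doublesum`) but
cannot reach self-similarity 1 (cross terms are below 1), so best-match
is the default and the identity property is only asserted for it.  A
patient with no biclusters has similarity 0 to everyone and 1 to
itself.  The class-distance ratio `D` (mean within-class over mean
between-class off-diagonal similarity) is provided as a separation
diagnostic.

## Classification (KNN-gated kernel SVM)

For a test patient, the `K` most similar training patients are selected
(similarity ties broken by training order).  A unanimous neighborhood
decides immediately; otherwise a linear soft-margin SVM is trained on
the neighborhood with the PPISim matrix as kernel, and the test patient
is classified by the sign of the decision function (an exact zero falls
back to the neighborhood's majority label, ties to the positive class).

The dual — maximize `Σα_i − ½ΣΣ α_i α_j y_i y_j K_ij` subject to
`0 ≤ α_i ≤ C`, `Σ α_i y_i = 0` — is solved by exhaustive pairwise
coordinate ascent (SMO) to a step tolerance of `1e-12`; on the ≤ `K`
point neighborhoods this is exact to well below the `1e-6` KKT residual
asserted in tests.  PPISim is not guaranteed positive semidefinite, so
each neighborhood kernel is first projected to the PSD cone by clipping
negative eigenvalues at zero.  The bias is the mean of `y_i − f_i` over
margin vectors, or the midpoint of the KKT-consistent interval when no
margin vector exists.  Defaults `K = 7`, `C = 1`; both can instead be
selected per training fold by an inner stratified CV over a grid
(`select_grid`), using the training-fold kernel.

*Evaluation.*  10 repetitions of stratified 4-fold CV (stratification
prevents single-class folds at the 25–50 patient scale).  The
discretization model, biclusters, network scores and kernel are
computed inside each training fold and applied to test patients (test
series are decoded with the training-fold model).  Normalization and
imputation are applied once to the whole dataset: they use no labels
and per-gene scaling is a fixed transform, so the leakage risk is
negligible against the cost of refitting scales per fold.  Metrics are
accuracy, precision, recall and F-measure with the good responder as
positive class, summarized as mean/sd over repetitions.  The ablation
harness reruns the identical folds with uniform bicluster weights
(network ignored), sharing the fitted models and biclusters, so the two
arms differ only in the weighting.  Early-stage evaluation truncates
every patient to the first `n ≥ 3` time points and repeats the CV.

## Synthetic cohorts

The generator emulates the shape of an interferon-beta response study:
by default 33 good and 19 bad responders, 70 genes, 7 time points, 3
states.  Genes form modules: *discriminative* modules (default two of
five genes) share a state program that differs between classes at every
time point of a window (default time points 2–5) and agree outside it;
*decoy* modules are expression-coherent within each patient but draw
their program independently per patient, so they carry no class signal
— and their genes receive no planted network edges; remaining genes
follow fixed per-gene random-walk programs shared by all patients.
Discriminative modules are wired as stochastic blocks at `p_in = 0.8`
over a background edge rate of `p_out = 0.04`, giving network densities
comparable to a curated interaction subnetwork over such a gene panel
(~100–120 edges).

Expression is `state + noise` with states one unit apart —
`noise_sd = 0.25` by default, i.e. a 4-sd separation between adjacent
levels; a uniform-noise variant probes model mismatch.  Cells are
masked missing independently at rate 0.05, always leaving at least one
present value per series.  Everything is reproducible bit-for-bit from
the seed.

What the generator does *not* emulate: platform effects (PCR vs
microarray scale differences), gene–gene correlation beyond shared
state programs, visit-level missingness (whole time points missing for
a patient), or label noise.  Passing benchmarks therefore show that the
pipeline recovers the structure it models, not that clinical data meet
these assumptions.

*Recovery criterion.*  At the default noise, the planted discriminative
modules are recovered in aggregate: the mean (over patients and planted
modules) gene-set Jaccard between a planted bicluster and its
best-matching extracted bicluster exceeds 0.8.  The aggregate is the
meaningful statement — at any positive noise a single decoded-state
flip in one gene of one patient removes that gene from the full-window
bicluster, so a universal per-patient bound cannot hold.

## Problem sizes used in the test suite

Oracle-equivalence checks run on hundreds of random instances small
enough for brute force (≤ 12 genes, ≤ 8 time points, ≤ 3 states for
biclustering; `Q^T ≤ 729` paths for decoding; ≤ 12-node networks for
the hypergeometric tail).  End-to-end benchmarks use the default
52-patient cohort with the full 10×4-fold protocol; the smaller unit
cohorts (8–14 patients, 16–30 genes) exercise the same code paths at
interactive speed.
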