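# Methods

This note documents the statistical model behind `mcrum`, the numerical
choices its implementation makes, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Binary CRUM

The classification relevance units machine models the positive-class
posterior as a logistic-sigmoid transform of a sparse kernel expansion,

P(C₊ | x) = σ(Σᵢ₌₁..M wᵢ k(x, uᵢ) + b),  k(x, u) = exp(−γ‖x − u‖²).

The defining feature is that the basis centers (relevance units) are fixed
*before* the supervised fit by unsupervised clustering of the pooled,
unlabeled features; the supervised problem is then a finite-dimensional
penalized logistic regression on the design Φ with Φ\_nm = k(x\_n, u\_m)
plus an unpenalized bias column.

**Fitting.** We minimize the penalized log loss
L(w, b) = −Σ\_n [t\_n log p\_n + (1 − t\_n) log(1 − p\_n)] + (α/2)‖w‖²
by damped Newton/IRLS: gradient max-norm tolerance 1e-8, at most 100 inner
iterations, step halving whenever a full Newton step would increase the
objective, IRLS weights floored at 1e-10, and a hard error if the
regularized Hessian solve fails. The bias is never penalized (standard for
intercepts; the model lists it separately from the kernel weights).

**Ridge weight.** α is not a user parameter. Between weight solves it is
updated by the evidence (MacKay) fixed point α ← γ\_eff/‖w‖² with
γ\_eff = Σ\_j λ\_j/(λ\_j + α), where λ\_j are the eigenvalues of the
unpenalized-loss Hessian restricted to the weight block (ΦᵀWΦ at the
current mode). The alternation starts at α = 1 and stops when α changes by
less than 0.1% relative, when the weights have been pruned to ‖w‖² < 1e-8
(signal-free data drives α → ∞ and the bias-only model is the fixed
point), or after 100 rounds (logged warning; the final iterate is
returned). A last weight solve at the accepted α guarantees the returned
coefficients are a stationary point, which the tests assert via the
gradient norm. α is clipped to [1e-10, 1e10] to keep the fixed point
finite in the perfectly-separable and perfectly-random corner cases.

The original CRUM literature specifies "structural risk under log loss
with an empirical-Bayes trade-off parameter" but not the exact update
order or priors; this reconstruction is the standard machinery consistent
with that contract, and the wine/iris benchmark results (below) land
within the published bands for this classifier family, which is the
behavior-level check available.

**Standardization.** Generic tabular features are z-scored per column
(parameters stored in the model) because the Gaussian kernel is scale
sensitive; k-mer frequency features are already on a common [0, 1] scale
and are used raw (`standardize=False`).

## Model selection

The number of relevance units M and the kernel width γ are chosen from the
unlabeled features alone. For each candidate M, K-means (Lloyd, best of 5
seeded random-point initializations) clusters the features; the clustering
is scored by an AIC under a hard-assignment isotropic Gaussian mixture
with shared variance σ² = SSE/(N·d), mixing weights n\_m/N, and
P = M·d + (M − 1) + 1 free parameters:

AIC = 2P − 2[Σ\_m n\_m ln(n\_m/N) − (N·d/2)(ln 2πσ² + 1)].

The probabilistic interpretation of K-means is genuinely open; the
hard-assignment mixture above is the simplest standard one, and only the
arg-min over M matters, not the absolute AIC. Ties go to the smaller M.
The default `auto` grid is the doubling sequence {2, 4, 8, …} capped at
min(512, N/2); a fixed M may be supplied instead (large sequence problems
favor a fixed, pre-chosen complexity — a few hundred units — over a long
grid search). The width is set to γ = 1/(2 d²\_max) with d\_max the
maximum pairwise distance between the selected centers; the same units and
γ are shared by all L binary classifiers of one multiclass model, which is
both cheaper than per-column selection and keeps the binary outputs on a
comparable scale for decoding.

## Coding matrices

A K×L matrix over {1, 0, Δ} is valid when (1) all rows and all columns are
unique, (2) no row is entirely Δ, and (3) every column contains a 1 and
a 0. One-versus-rest is the K×K identity pattern; all-pairs enumerates the
K(K−1)/2 unordered pairs in lexicographic order (1 for the smaller-index
class, 0 for the larger, Δ elsewhere). Row distances use the modified
Hamming cost: 0 for equal non-Δ symbols, 1 for unequal non-Δ symbols, ½
whenever either symbol is Δ — by that literal rule d(Δ, Δ) = ½, which only
ever affects row-vs-row ranking (predictions contain no Δ).

Random codes sample entries uniformly over {1, 0} (dense) or with
probabilities (½ Δ, ¼ 1, ¼ 0) (sparse — the established convention),
resampling invalid columns within a bounded retry budget; 100 candidates
are generated by default and the one with the **largest** minimum pairwise
row distance is kept (maximum row separation is the classical ECOC design
criterion), ties to the earliest candidate. Literal uniqueness only is
enforced — a column and its bit-complement are distinct. The candidate
pool is re-enumerable from the seed so the selection is auditable.

## Decoders

*Hard*: binarize the outputs at 0.5 and return the nearest codeword row,
ties to the smallest class index.

*Naive*: assume the L binary classifiers err independently; the class
score is the log-product of gᵢ (codeword 1) or 1 − gᵢ (codeword 0) over
non-Δ entries, normalized by a max-subtracted softmax (identical to
normalizing the raw products, numerically safer). Outputs are clipped to
[1e-12, 1 − 1e-12] before logs. Cost is one pass over the code — linear in
L — which is the point: the decoder runs per input at prediction time.
The independence assumption degrades on random codes (where one training
point informs many columns); the benchmark comparison below quantifies
when that matters.

*Generalized Bradley-Terry*: find p minimizing the weighted negative
log-likelihood −Σᵢ Nᵢ[r̂ᵢ log(qᵢ₊/qᵢ) + (1 − r̂ᵢ) log(qᵢ₋/qᵢ)], where
qᵢ₊/qᵢ₋/qᵢ are sums of p over column i's positive/negative/either set and
Nᵢ is the column's training count. Starting uniform, each sweep applies
the canonical multiplicative update

p\_k ← p\_k · [Σ\_{i: k∈Iᵢ₊} Nᵢ r̂ᵢ/qᵢ₊ + Σ\_{i: k∈Iᵢ₋} Nᵢ(1 − r̂ᵢ)/qᵢ₋]
/ [Σ\_{i: k∈Iᵢ} Nᵢ/qᵢ]

and renormalizes; q terms are floored at 1e-12. Iteration stops when the
largest per-class change drops below 1e-8 (our choice; only the
1000-sweep cap is inherited from the method's usual protocol) or at 1000
sweeps. Non-convergence is reported in the result object, not raised —
under general decompositions the iteration need not converge. The
objective trace is recorded so its monotone decrease is assertable.

## Multiclass orchestration

Training walks the coding matrix column-wise: classes marked 1 form the
positives, 0 the negatives, Δ rows are omitted, and a binary CRUM is fit
on that partition with the shared units and γ. An empty side of any
partition is an error naming the column. N\_i (positives + negatives) is
stored per column for GBT weighting. Prediction computes all L binary
posteriors once and hands them to the chosen decoder; with a soft decoder
a rejection threshold t ∈ [0, 1) leaves the input UNCLASSIFIED unless the
argmax posterior reaches t (hard decoding has no posterior, so any t > 0
is an error). Models serialize to schema-versioned JSON with
full-precision floats; save → load → save is byte-identical, and training
is deterministic given the seed.

## Sequence features

Sequences are canonicalized to uppercase RNA (T → U); characters outside
{A, C, G, U, N} cause the record to be skipped with a warning. The feature
vector concatenates per-k normalized k-mer counts for k = 1…5 in
lexicographic order (A < C < G < U), 1364 dimensions total. Normalization
is per k-block — each populated block is a probability simplex — rather
than one global division; windows containing N are skipped and the
denominator adjusted, preserving the simplex property. Background
sequences longer than the fragment length (default 20 nt, inside the
miRNA/piRNA length overlap) are replaced by a uniformly random contiguous
fragment whose choice depends only on the run seed and the record id.
Classes can be downsampled to the minority count to form a balanced
training set. Redundancy reduction of real collections (CD-HIT at 80%
identity) is deliberately out of scope — it is an external preprocessing
tool.

## Evaluation protocol

ROC curves for a K-class classifier nominate one class as positive and
pool the rest: TP = positives called positive; FN = positives called
anything else **or rejected**; FP = negatives called positive; TN = all
other negatives, *including* negatives confused with a different negative
class and rejected negatives (they were correctly kept out of the positive
class). FPR = FP/(FP + TN), TPR = TP/(TP + FN); both denominators are
threshold-invariant, so TPR and FPR are non-increasing and the
unclassified fraction non-decreasing along the default sweep (0.30 → 0.99,
step 0.01, 70 points, posteriors decoded once). Cross-validation uses
seeded stratified folds (stratification is our choice; it keeps every
class present in every fold) and counts UNCLASSIFIED as an error when a
threshold is set; the benchmark protocol uses threshold 0, where every
input receives its argmax class.

## Synthetic data

Three seeded, bit-reproducible generators stand in for external datasets:
isotropic Gaussian blobs (generic feature tables; the default test layout
separates centers by 10σ so any sound classifier should be near-perfect —
the tests check machinery, not difficulty); Bradley-Terry-consistent
binary outputs (r̂ᵢ = qᵢ₊/qᵢ under a known p, making exact recovery the
correct answer for the GBT decoder); and composition-biased RNA sequences
drawn from per-class dinucleotide Markov chains, a convex mix between the
uniform chain and a class-specific Dirichlet draw. First-order chains were
chosen over i.i.d. bases so that k > 1 features carry real signal and the
full 1364-dimensional featurizer is exercised. Bias strength 0 makes all
classes identically distributed (accuracy must fall to chance); the
generators make no attempt to mimic real miRNA/piRNA biology (seed motifs,
5′-U bias, secondary structure) — conclusions from passing tests are about
the algorithmic machinery, not about biological performance.

## Problem sizes and benchmarks

The test suite and the acceptance script run on deliberately small
problems chosen so that correctness properties are sharp: 100 points per
class and M = 4 units for blob tasks, 102 recovery instances for GBT
(K ∈ {3, 5, 10}), 1000 random coding-matrix instances for the decoder
oracles, and 60–80 sequences per class for the sequence workflow. The two
bundled benchmark tables (wine: 178×13, iris: 150×4) are run at full size
with 10-fold cross-validation and automatic M/γ selection; with AP or OVR
codes and naive decoding the mean accuracies land within one standard
deviation of the published results for this classifier family (wine ≈
97.8 ± 2.9 %, iris ≈ 96.0 ± 5.6 %), which is the strongest available
end-to-end check of the CRUM reconstruction.

## Known limitations

* Only the Gaussian kernel is implemented (the kernel field is a hook).
* The direct multiclass (softmax) variant of the CRUM is deliberately not
  provided: the (MK + 1)-dimensional Hessian makes it impractical for the
  large-scale settings this package targets.
* The naive decoder's independence assumption fails on random dense/sparse
  codes; GBT is the safe choice there, at iterative cost per input.
* The GBT iteration has no general convergence guarantee; the result
  carries `converged`/`n_iter` so callers can inspect it.
* No AUC summaries are computed; the ROC table is the deliverable.
* Feature tables are dense in memory; very large sequence collections
  should be featurized in batches.
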