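# Methods

## Sparse coding (OMP)

Signals are coded against a dictionary ``D`` with unit-norm columns by
orthogonal matching pursuit: at each step the atom with the largest absolute
correlation with the residual is selected (ties broken toward the lower
column index, for determinism), and the coefficients on the whole current
support are refit by least squares, so the residual is exactly orthogonal to
every selected atom (contract tolerance ``1e-8·‖x‖₂``).  Iteration stops at
the sparse factor ``k``, or earlier when the residual norm falls to the
optional ``residual_tol`` or to numerical zero (which is how a zero signal
yields an empty code).  The classifier layers use the ``k``-form budget only.
If a support's Gram matrix is singular the refit falls back to the
pseudoinverse with a logged warning.  The iteration count is additionally
capped at the signal dimension, beyond which the least-squares system is
underdetermined and the residual already zero.

## Analytic dictionary

The overcomplete DCT dictionary has entries ``cos(π·i·j/cols)`` for row
``i``, column ``j``; non-constant columns are mean-centered and all columns
scaled to unit norm.  Centering is skipped when it would annihilate a column
(e.g. the degenerate one-row dictionary, where every column is the constant
1).  Width defaults to twice the number of rows.  Overcompleteness
(``cols > rows``) is enforced at construction.

## K-SVD

`ksvd_learn` alternates two stages per sweep:

1. **Atom update** — for each atom used by at least one training signal, the
   restricted error matrix (residuals of the using signals with that atom's
   contribution added back) is approximated by its best rank-one factor via
   SVD; the atom and its nonzero coefficients are replaced jointly.  The sign
   is fixed by forcing the atom's largest-magnitude entry nonnegative, so
   learned dictionaries are bit-comparable across runs.  Atoms used by no
   signal are replaced by the currently worst-reconstructed training signals
   (one distinct signal per dead atom, largest residual first; switchable to
   ``keep``).  Unused atoms carry zero coefficients, so replacement leaves
   the objective untouched.
2. **Sparse coding** — every signal is re-coded by OMP against the updated
   dictionary, with a warm-start safeguard: a signal keeps its previous code
   whenever the fresh greedy code reconstructs it worse.  Greedy OMP offers
   no monotonicity guarantee on its own, and without the safeguard the
   logged objective can bump upward by several percent between sweeps; with
   it, the per-sweep objective ``Σᵢ‖xⁱ − Dαⁱ‖₂²`` is non-increasing by
   construction, which the tests assert.

The default schedule is 30 sweeps with sparse factor 5 — small clinical-scale
training sets (tens of signals) converge well within that budget.  Training
samples are normalized once upstream and never re-normalized between sweeps.

## SRC and SRC-AL

SRC builds one unit-norm column per training sample, grouped into class
blocks; prediction codes the normalized test sample against the full
dictionary and returns the class with the smallest class-restricted
reconstruction residual.  A warning is logged when the sample count is below
the dimension, the regime where this data-implemented dictionary cannot be
overcomplete.

SRC-AL augments each normalized training sample with its one-hot label
(label magnitude 1.0 by default, configurable through ``label_weight``); the
combined ``(m+c)``-vector is deliberately **not** re-normalized, keeping the
label energy identical across samples.  The DCT dictionary over the
augmented space is K-SVD-refined; the learned dictionary records
``split_row = m``.  At prediction time the signal block's columns are not
unit-norm even though the full columns are; by default they are re-normalized
for coding and the coefficients rescaled back, so the label vector
``L_y = D'_lw α_y`` is computed on the original column scale (coding against
the raw block is available via ``renormalize_upper=False``).  Ties in both
decision rules (minimum residual, maximum ``|L_y|``) resolve to the earlier
class in ``class_order``.  The same sparse factor is used at train and test
time.

## Preprocessing

Variable-length breath-by-breath series are mapped to a common length by
linear interpolation on the closed index interval ``[0, L−1]`` (endpoints
preserved exactly), then l2-normalized.  Default target lengths are the
longest series observed per CPET phase — 270 (exercise), 81 (warm-up), 195
(recovery) — and phases may not be mixed within one dataset, since a
dictionary learned at one dimension is not transferable to another.  No
smoothing is applied before interpolation.  A zero-norm series is rejected
as degenerate rather than silently normalized.

## Responder labeling and the clinical baseline

BP throughout is the sum of systolic and diastolic pressure (mmHg).  The
percent change rate uses the absolute convention ``|MBPB − MBPA|/MBPB·100``
for labeling; z-scores standardize against the cohort mean and **population**
standard deviation (divide by n).  The population convention reproduces the
reference cohort's printed z-scores to within ±0.005, whereas the sample
convention does not — both are exposed via ``std_mode``.  The cohort-average
change rate is conventionally reported under the **signed** convention
``(MBPB − MBPA)/MBPB·100`` (the absolute-rate mean differs in the third
digit); ``change_rate`` exposes both modes explicitly.  The baseline
predictor labels a patient weak iff ``PEBP − R6BP < 0`` (a boundary patient
with ΔBP = 0 is predicted strong).  F1 uses strong as the positive class.

## Evaluation harness

Leave-one-out cross-validation re-fits the classifier — including the full
K-SVD run for SRC-AL — on every fold of n−1 samples.  The sparse-factor grid
search selects k by the same unnested LOO whose accuracy it reports
(optimistic; the report records its configuration so a nested protocol can
be distinguished).  Accuracy ties prefer the smallest k.  Undefined
precision/recall/F1 (no positive predictions or truths) are reported as 0
with a warning rather than raised.

## Synthetic cohort generator

The generator emulates exercise-phase oxygen-pulse curves: on normalized
time ``t ∈ [0,1]``, strong responders follow the saturating ramp
``a·t/(t+b)`` (a = 1, b = 0.3) — the rising oxygen pulse of preserved
cardiopulmonary reserve — while weak responders follow the same ramp only up
to a plateau at ``τ = 1/(1+e)`` of the test and decline linearly with slope
``0.8·e`` afterwards, the oxygen-pulse flattening associated with limited
stroke-volume reserve (``e`` = effect size; at e = 0 the classes coincide
exactly).  Measurement noise is stationary AR(1) with marginal sd 0.1 and
autocorrelation 0.5 by default, reflecting the strong breath-to-breath
correlation of CPET measurements.  Series lengths are drawn uniformly from
85–270 points so the resampling pipeline is always exercised; the default
cohort is 12 patients per class.

A plain curvature or amplitude shift was rejected as the class effect:
l2 normalization removes amplitude entirely, and saturating ramps of
different curvature stay within ~8° of each other — less than the angular
scatter the default noise induces — so no classifier could separate them.
The plateau-and-decline contrast puts the class signal in a shape feature
that survives normalization.

What the generator does **not** emulate: cross-correlated multi-indicator
structure, heteroscedastic noise over the ramp, artifacts (coughs, mask
leaks), or cohort-level covariate shift.  Passing the synthetic benchmarks
therefore demonstrates that the pipeline recovers a shape-coded class signal
under autocorrelated noise at clinical sample sizes — not that comparable
accuracy would be reached on hospital CPET data.

## Planted benchmarks

The sparse-recovery benchmark plants k-sparse signals (k ≤ 3) with decaying
coefficient magnitudes {2.0, 1.0, 0.5} and random signs in dictionaries of
size 10×20 whose mutual coherence is driven below 0.35 by alternating
Gram-clipping with a rank-10 spectral projection
(`make_low_coherence_dictionary`).  Greedy coders carry recovery guarantees
only for incoherent dictionaries; plain Gaussian draws at this size have
typical coherence ≈ 0.8 (the Welch lower bound is 0.23), where OMP and the
exhaustive least-squares oracle part ways on a few percent of problems even
at moderate coefficient spread.  Under the benchmark conditions OMP matches
the oracle support on every trial across seeds.  The K-SVD benchmark trains
on 50 such planted signals from a Gaussian dictionary and checks the
objective decreases monotonically to below half its initial value.

## Numerical conventions

Orthogonality tolerance ``1e-8`` (relative); unit-norm assertions at
``1e-10``–``1e-12``; residuals at or below ``1e-12·max(‖x‖,1)`` count as
exact reconstructions.  All randomness flows through
``numpy.random.default_rng`` seeds; LOO and grid search are fully
deterministic given data and configuration.

## Known limitations

- The grid search is unnested; with 24 samples the reported accuracy at the
  selected k is optimistically biased.
- K-SVD cost grows with dictionary width; at the default exercise-phase size
  (272 × 544 atoms), a full 24-fold LOO with per-fold re-learning takes a
  few seconds of CPU, which bounds how wide a grid is practical.
- The label-augmentation weight (1.0) and the test-time re-normalization of
  the signal block are conventions, not derived quantities; both are
  switchable and can matter on real data.
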