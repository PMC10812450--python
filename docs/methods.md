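# Methods

## The data and its schema

The study design samples sugarcane straw from two growing areas in São
Paulo state (Guariba and Valparaíso) on seven collection dates between
June and November 2020, crossing each area × date with a high
(4–11%) and a low (0–4%) borer-infestation batch: 28 harvest
conditions in all. Each batch carries a variety (from a closed
nine-member catalog) and a ratoon/harvest number (1–7). Per-compound
concentrations (µg/g dry extract) are recorded for the compounds a
batch's LC-MS run detected; a `-` cell means not detected and
contributes zero to class sums — the only completion consistent with
summing classes over detected compounds. Antioxidant capacity is an
IC50 (mg/mL) per batch for ABTS and DPPH; eight batches per assay were
not determined and stay missing (they are kept in the dataset but
excluded from any model fitted to that response).

Compound names are matched exactly after NFKC unicode normalization and
whitespace collapse. There is deliberately no fuzzy matching: a
misspelled compound surfaces as a lookup error instead of being silently
assigned to the wrong polyphenol class. Equality tests on concentrations
use a 1e-6 µg/g tolerance (the tables print one decimal).

Two transcription caveats are inherent to the source tables and are
surfaced rather than resolved: the per-batch condition metadata in the
antioxidant table occasionally disagrees with the concentration-table
column headers (the condition table is the single complete listing and
is treated as authoritative), and the running text's extrema sometimes
differ from the table cells (the tables win).

## Response-surface model

Factors are coded onto [−1, +1]: collection date as days since the
earliest collection, affinely mapped; area as {Guariba: −1,
Valparaíso: +1}; variety as its ordinal index in the catalog listing,
affinely mapped; infection % and harvest number as affine maps of the
observed range. Variety is nominal, and treating it as one ordinal
column is a known caveat of the polynomial route (the network route
one-hot encodes it instead); the coding lives in one `FactorCoding`
object so alternatives are a single configuration away.

The term set is fixed at 20: intercept, five linear, four quadratic
(X₃² excluded — a two-level factor's square is collinear with the
intercept) and all ten pairwise interactions. The fit is ordinary least
squares; implementation choices:

- minimum-norm solution with a warning on rank-deficient designs, and
  the non-identifiable terms (pivoted-QR columns beyond the rank) are
  flagged with NaN standard errors. The study tables themselves trigger
  this: infection is recorded only as a high/low class, so the coded
  infection factor is binary and its quadratic is inestimable on the
  real data;
- R² uses a mean-centered total sum of squares and is defined as 0
  (with a warning) for a zero-variance response;
- coefficient p-values come from two-sided t-tests with n − rank(X)
  degrees of freedom; significance stars use the printed inclusive
  thresholds (p ≤ 0.05, 0.01, 0.001);
- prediction intervals use the OLS variance of the mean response at the
  queried point. Models seeded from the published coefficient table
  carry no covariance, so they yield point predictions without
  intervals.

The normal equations Xᵀ(y − Xβ̂) = 0 are enforced to 1e-8 in tests, and
the whole fit is cross-checked against statsmodels OLS (β, se, p, R²)
as an independent oracle.

## Desirability optimization

Each response's desirability ramps linearly (weight 1 by default)
between the lowest and highest observed value of that response, the
default range choice; IC50 responses are configured to minimize, since
a lower IC50 means stronger radical scavenging. The composite is the
weighted geometric mean — the standard Derringer form — so one fully
undesirable response zeroes the candidate. The optimum is found by
exhaustive search over the Cartesian product of observed factor levels
(dates, varieties, areas, harvests are discrete in this design), with
infection gridded at 0.5% steps across its observed range; a continuous
optimizer could return a variety that does not exist. Ties break to the
lexicographically smallest coded point. If a response's prediction at
the optimum leaves its observed range the result carries a hull-exit
warning instead of being trusted as an extrapolation.

## Network model

A single-hidden-layer perceptron with 20 inputs on the study design:
one-hot collection dates (7), the full nine-variety catalog (one-hot),
the two areas (one-hot), plus infection % and harvest number
standardized to zero mean/unit variance (on the training rows when a
split is supplied; on all provided rows otherwise). Hidden sizes 3–5
and four activation choices (identity, logistic, tanh, exponential) are
searched; the exponential and logistic pre-activations are clamped at
±50 to guard overflow, and a non-finite final loss is an error naming
the network.

Training minimizes the sum-of-squares error with BFGS using an analytic
backpropagation gradient (verified against finite differences in
tests), stopping at gradient max-norm ≤ 1e-6 or 500 iterations.
Weights initialize uniform on [−0.5, 0.5] from a seed — a small
symmetric init appropriate for a quasi-Newton-trained shallow network.
If the optimizer ends above the initial loss the initial weights are
kept, so the returned loss never exceeds the initialization. Targets
are standardized internally and restored on prediction.

Data are split 70/15/15 (train/validation/test) by a seeded
permutation; validation and test sizes round half-up and the remainder
goes to training, which reproduces the published 19/4/4 partition at
n = 27. The automated search trains 20 candidates and retains the top 5
by mean validation Pearson r, tie-breaking toward fewer hidden neurons.
Each candidate's init seed derives from the master seed and the
candidate's canonical position (spec plus occurrence index), so the
retained set is invariant to the order candidates are supplied.
A single fixed split mirrors the published validation protocol;
leave-one-out would be more exhaustive at this sample size and can be
layered on by callers, but it is not the default.

Garson importance partitions absolute connection weights: input x's
share through hidden neuron b is |W_xb| / Σ_a |W_ab| weighted by
|V_b|, summed over hidden neurons and normalized over all inputs (the
standard Garson normalization; the importances sum to one by
construction). One-hot columns fold back into their parent factor by
summation. The measure is invariant to positive rescaling of the
output weights and to hidden-neuron permutation — both tested.

## Synthetic data

The generator emulates the study: by default it reproduces the 28
harvest conditions exactly, draws each response from the 20-term
polynomial with the published coefficient columns as true β, and adds
homoscedastic Gaussian noise with per-response SDs equal to the
published fit RMSEs (7.455, 38.418, 8.948 µg/g; 0.04, 0.12 mg/mL) so
synthetic fits land in the reported fit-quality regime. The design is
deterministic — only responses are stochastic — and replicates extend
it (n = 56 at two replicates).

Because the published tables record only the infection class, the
generator assigns each synthetic batch its own infection level, spread
evenly over the stated class ranges (high 4–11%, low 0–4%). This
mirrors the real sampling — each field batch had a precise infestation
percentage — and keeps the infection quadratic identifiable, which the
class-only real data cannot do.

An optional distortion `amplitude · sin(π·X₅) · X₁` adds smooth
curvature no second-order polynomial can represent; any smooth
non-polynomial would serve. On undistorted surfaces the polynomial's
test R² matches or beats the network's in the large majority of seeded
runs; at strong distortion (amplitude 2000 µg/g against a ≈7.5 µg/g
noise SD) the ordering reverses — the network's advantage emerges only
when the generative surface actually leaves the polynomial family.
The noise model is an assumption, not an inference from the data: the
source reports no residual diagnostics, and Gaussian homoscedastic per
response is the simplest consistent choice.

What passing synthetic tests does *not* show: robustness to
heteroscedastic or correlated noise, to compound-level measurement
error (synthesis is at the class-response level), or to designs other
than this 28-condition plan.

## Problem sizes and numerical choices

Tests run at the study's own scale: 28-condition designs (56 rows with
two replicates), 20-candidate network searches at 150–300 BFGS
iterations, 200-replicate coverage simulations, and 20-seed
head-to-head comparisons — sizes chosen to exercise every code path at
the scale the method is meant for. Interval-coverage acceptance demands
each coefficient's 95% CI cover the truth in ≥ 90% of 200 replicates;
observed coverage is 93–96%. Deterministic artifacts (JSON with sorted
keys, fixed float formatting) make pipeline reruns byte-identical under
a fixed seed, which the manifest's sha256 hashes verify.

## Known limitations

- The ordinal variety coding imposes an arbitrary order on a nominal
  factor; coefficients on X₂ should be read as descriptive, not causal.
- With 20 terms on 28 (or fewer, for IC50) observations, the polynomial
  is near-saturated; adjusted R² and residual degrees of freedom are
  small and the IC50 fits are essentially interpolating.
- The published per-batch infection percentages are unavailable, so the
  real-data infection factor is binary and its quadratic inestimable.
- The desirability optimum can sit at a hull-exit point where the
  polynomial extrapolates; the warning should be heeded rather than the
  number trusted.
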