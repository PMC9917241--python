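# Methods

## Model

A quasi-SMILES string is treated purely as a sequence of codes: every
bracketed span `[...]` is one code (element, charged species, or
condition code such as `[c200,00]` — European decimal-comma notation
for 200.00 µg/mL, never interpreted numerically), and every other
character (`O`, `=`, `.`, `(`, `)`) is a code by itself.  Codes are
case-sensitive; whitespace is rejected.  Tokenization is total and
reversible: concatenating the tokens reproduces the input exactly.

The descriptor of a record is the sum of its codes' correlation
weights, counted with multiplicity — two `[Al]` tokens contribute the
`[Al]` weight twice.  Multiplicity is what makes the concentration
offsets of the fitted model skeleton-independent constants even though
dioxides and sesquioxides differ in skeleton code counts; the packaged
calculated column shows exactly this signature, which the test suite
checks.  The endpoint model is a single least-squares line from
descriptor to endpoint, fit on the active training set only.

Records are split into active training (A: weights are fit here),
passive training (P: checks transfer to strings not used for fitting),
calibration (C: detects overtraining), and validation (V: untouched
until final assessment), each about 25%.  The splitter is a seeded
Fisher–Yates shuffle followed by contiguous near-quarters in the order
A, P, C, V.

## Rare codes and unseen codes

A code occurring fewer than `T` times in the active training set is
rare and is pinned at weight exactly 0 (default `T = 1`: codes absent
from the active set).  At prediction time an unknown code likewise
contributes 0, and the record is flagged for the applicability-domain
report.  Under the published first split, the Ge, Hf and Ti element
codes never occur in an active-training row, so all three dioxides
collapse onto identical predictions at matching concentrations — a
degeneracy visible in the packaged calculated column, and a useful
structural oracle.

## Statistics

* R² is the squared Pearson correlation of observed vs calculated
  (verified against the packaged per-set columns at 4-decimal
  agreement; the 1 − SSres/SStot alternative disagrees on the P, C and
  V sets).
* CCC is Lin's concordance with population (1/n) moments.
* RMSE uses the sample (n−1) denominator.  This convention, with
  one-decimal truncation, matches all four published per-set values
  simultaneously; the plain 1/n form matches none.
* F = r²(n−2)/(1−r²) for the one-predictor regression.
* IIC = r · min(MAE⁻, MAE⁺)/max(MAE⁻, MAE⁺), the one-sided mean
  absolute errors taken over negative vs non-negative residuals
  (observed − calculated).  If one side is empty the ratio is 0 and
  IIC = 0; a perfect fit returns 1.
* CII = 1 − Σ_k max(0, R²₋k − R²): each point whose deletion raises
  the set's R² "protests" by the increase.  Computed from downdated
  sufficient statistics in O(n); a brute-force n-pass oracle in the
  test suite agrees to 1e-12.
* Q² is the leave-one-out cross-validated R² of the one-variable
  regression, via the exact hat-matrix identity for simple regression
  (agrees with an explicit refit loop to 1e-12).  Q² of observed ~
  calculated equals Q² of observed ~ descriptor because the calculated
  column is an affine image of the descriptor and simple-regression
  LOO is invariant under affine predictor maps.

## Monte Carlo optimization

Weights start at 1.0 for every non-rare code (or uniform [0.5, 1.5]
in randomized multi-run mode).  One epoch visits each non-rare code
once in seeded random order.  A proposal perturbs the visited code's
weight by `U(−step, step) · 10^U(−2, 1)` — a multi-scale draw whose
large moves escape shallow local optima and whose small moves refine —
and, with probability 1/2, jointly perturbs a second random code,
which lets the chain traverse the ridges that co-occurring (hence
correlated) codes create in the target surface.  Plain single-scale,
single-coordinate proposals demonstrably freeze: on noiseless
synthetic data the target value stayed bit-identical from epoch 300 to
3000 at validation R² ≈ 0.49, versus 1.00 with the scheme above.

A proposal is accepted iff the target function, recomputed with the
endpoint line refit on the active set, does not decrease; accepted
target values are therefore non-decreasing within a run.  Degenerate
proposals (zero descriptor variance on A, undefined correlations) are
rejected, never fatal.

Defaults: `T = 1`, `N = 300` epochs, `step = 0.5`, patience 30.  The
run stops early once the calibration R² has gone `patience` epochs
without a new best, and returns the final accepted state — at most
`patience` epochs past the calibration optimum.  (Returning the
arg-max-calibration snapshot instead was tried and rejected: early
noise spikes of calibration R² get selected and yield undertrained
weights.)  TF1 uses the calibration set for both IIC and CII.

Interpretation caveat: the endpoint model is invariant under negating
all weights together with C1, so a raw weight sign means nothing
across independently initialized runs.  Promoter classification
therefore reads sign(weight · C1) — the direction the code actually
moves the endpoint — and randomized starts are kept positive so runs
begin in the C1 > 0 convention.

Near a perfect fit TF1 is frustrated: the IIC ratio term rewards
balancing signed residuals and fights the last correlation gains, so
noiseless-recovery experiments use TF0 (runs plateau at V R² ≈ 0.98
under TF1 vs 1.00 under TF0).  On the real data the two target
functions give statistically indistinguishable validation quality
(means over 20 seeds within 0.02).

## Applicability domain

The statistical defect of a record sums, over its codes with
multiplicity, `|P_A − P_C| / (N_A + N_C)`, where `P_X` is the code's
share of all code occurrences in set X and `N_X` its raw count; a code
absent from both sets contributes a fixed penalty (default 1.0).  A
record is out of domain when its defect exceeds twice the mean defect
of the training (A and P) records.  The published outlier percentages
come from an externally defined defect formula, so only qualitative
agreement is expected; under the published first split this
implementation flags 23% of the validation set (published: 27%).

## Synthetic data

The generator emulates the real data's statistical structure: four
skeleton templates (dioxide `O={e}=O`, sesquioxide `O={e}O{e}=O`,
monoxide `{e}=O`, mixed `{e}=O.O={e}O{e}=O`), one element code per
skeleton drawn from `[E0], [E1], ...` with each element reused across
the four templates, and four concentration codes appended last with
monotonically decreasing true weights (higher dose, lower viability).
Element reuse matters: with single-use elements about a third of them
miss a random active set entirely, become rare, and make noiseless
recovery impossible by construction.  Endpoints follow
`c0 + c1 · Σ true_weights + N(0, noise_sd)` with defaults c0 = 60,
c1 = 8, element weights U(−3, 3), noise_sd = 0.

What passing synthetic tests show: the tokenizer, descriptor,
optimizer and metrics are internally consistent and the optimizer can
recover an exactly additive signal.  What they do not show: robustness
to the non-additivity of real dose–response data (e.g. sharp viability
collapse between adjacent concentrations), which bounds real-data
validation R² well below 1.

## Known limitations

* Model capacity is strictly additive in code counts; strongly
  non-additive dose–response records are fit poorly no matter the
  optimizer, and which records land in the validation set therefore
  dominates the validation R² of a random split.  Fitting the additive
  model to all 120 records and scoring the validation subset in-sample
  gives R² between 0.47 and 0.88 (mean 0.71) across 40 random splits —
  an upper envelope on what any training protocol can reach.
* Only single-code weights are implemented; no pairwise or triple code
  correlation attributes.
* The optimizer is a greedy stochastic search: different seeds give
  different, roughly equally good weight vectors.  Per-code weight
  values are not identifiable (only the ensemble sign pattern is
  interpreted); an overall affine freedom is absorbed by C0 and C1.
* Splits are plain random; no stratification by activity or oxide.
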