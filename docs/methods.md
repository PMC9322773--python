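# Methods

## Model overview

`multilstm` predicts gene expression at an unobserved time point of a
short expression time course by a decompose–forecast–recombine scheme:
the gene × time matrix (minus the target column) is normalized,
concatenated into a single 1-D series, split by empirical mode
decomposition (EMD) into oscillatory components of decreasing
frequency, and each component is continued one step past each gene's
last observation by its own LSTM; the component forecasts are summed
and de-normalized.  The scheme rests on two properties: EMD is
*complete* (components sum back to the input exactly, so recombination
introduces no systematic error) and each component is *smoother and
narrower-band* than the raw series, so a small forecaster can learn its
dynamics.

Reverse prediction (the 0 h, undegraded level from later samples) is
implemented by time-reversing every gene's trajectory before assembly,
so the target column is always the last one in model coordinates;
forward prediction uses the natural order.

## EMD

Sifting follows the classical recipe: cubic splines through the
interior maxima and minima give upper/lower envelopes u(t), v(t); the
candidate is updated as h ← h − (u+v)/2 until it satisfies the two IMF
conditions — (1) the counts of interior extrema and zero crossings
differ by at most one and (2) the envelope mean is numerically zero —
or until the Cauchy statistic SD_k = Σ(h_{k−1}−h_k)²/Σh_{k−1}²
falls below `sd_threshold` *while the IMF conditions already hold*, or
an iteration cap is reached.  Coupling the SD stop to the IMF
conditions is deliberate: a bare SD stop can return components that
violate the extrema/zero-crossing count, and the package guarantees
every returned IMF passes `is_imf`.  Condition (2) is relaxed to
max|m(t)| ≤ `envelope_tol` · max|c(t)|, since exact zero envelope mean
is unattainable on sampled data.

Each extracted IMF is subtracted from the running residual
(r_i = r_{i−1} − c_i), so completeness holds to float accuracy by
construction; decomposition stops when the residual has fewer than one
maximum or one minimum, or at `max_imfs`.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| `sd_threshold` | 0.2 | the conventional 0.2–0.3 sifting range |
| `max_sift_iter` | 50 | over-sifting guard |
| `max_imfs` | ⌈log₂N⌉+1 | dyadic-filterbank capacity of EMD |
| `boundary_policy` | `extrapolate` | see below |
| `envelope_tol` | 0.5 | loose numeric relaxation of the zero-mean condition; the SD criterion, not this bound, does the fine stopping work |

### Boundary policy

Spline envelopes need knots beyond the signal ends.  The widely used
mirror scheme (reflect the two nearest extrema about each endpoint,
anchoring the endpoint itself when it protrudes) folds any local trend
back on itself and biases the envelope mean near the boundaries; on a
two-tone benchmark (5 Hz + 0.5 Hz, 1000 samples over 2 s) that bias
caps the slow-tone recovery at correlation ≈ 0.8.  The default policy
therefore *extrapolates*: knot positions are mirrored, but knot values
follow the straight line through the two nearest same-kind extrema,
clipped to the observed signal range (the clip prevents envelope
blow-up when the reflection distance is large relative to the extrema
spacing, e.g. on trend-dominated residuals).  With this policy both
tones are recovered at correlation > 0.999 and sifting converges on
random walks.  `mirror` (Rilling-style) and `clamp` (endpoints as
extrema) remain selectable.

Other numerical choices: plateau extrema report their midpoint (ties
to the lower index); an exact-zero sample counts as one zero crossing
only when its nonzero neighbours have opposite signs; the zero series
is an IMF by convention; constant series under min-max normalization
map to zero and invert to the recorded constant.

The Hilbert instantaneous spectrum (analytic-signal modulus and scaled
derivative of unwrapped phase) is provided per IMF; the highest
instantaneous frequency is read off the interior 80% of samples
because the discrete Hilbert transform rings at the borders.

## LSTM

A single LSTM layer (input/forget/output gates, memory cell, scalar
linear head on the hidden state) is implemented directly in numpy.
The printed recurrences are followed with one correction: the memory
update is taken as c_t = f_t⊙c_{t−1} + i_t⊙c̄_t (the previous cell
state enters through the forget gate; a version with c_t on both sides
would be circular).  Training minimizes full-batch MSE over sliding
(window, next-value) pairs with hand-derived backpropagation through
time, adaptive-moment updates (β₁ = 0.9, β₂ = 0.999), and global-norm
gradient clipping at 1.0.  Analytic gradients are verified against
central finite differences (relative error < 1e−5) in the test suite.

Topology and training defaults — window L = 3 (gene segments are 11
points; short windows maximize the number of training pairs), hidden
size H = 32, learning rate 1e−2, 200 epochs, uniform ±1/√H weight
initialization with zero biases except a forget-gate bias of 1 — are
modest, configurable choices; nothing in the underlying recurrences
prescribes them.  A fixed seed yields a bit-identical parameter
trajectory and loss history.

## Pipeline detail

**Normalization** is fit per gene on the training columns only
(min-max to [0,1] by default; z-score and global scope available) and
recorded for exact inversion; the withheld column never influences the
normalization.

**Decomposition scope.**  By default the EMD runs on the *complete*
concatenated series — including the target column, normalized with the
training-only record — while every forecaster is trained exclusively on
windows that exclude the withheld positions (`decompose_scope="full"`).
The fully leak-free alternative (`"train_only"`, decompose only the
training columns) is implemented and selectable, but it is *not* the
default for an empirical reason: with per-gene normalization and
gene-major concatenation the withheld positions sit exactly at the
sharp resets between gene blocks, and the components of the
training-only series systematically bend away from the truth there
(the mid-frequency IMFs oscillate with the gene period).  Under that
scope the recombined forecast of *any* per-component one-step
regressor — LSTM or a regularized linear model — is biased low by
≈ 0.4 on the normalized scale and carries almost no gene-level
information, losing clearly to last-observation persistence.  With the
full-series decomposition the components at the withheld positions are
well-defined smooth targets, per-component forecasting is meaningful,
and the recombined forecast beats both baselines on essentially all
synthetic panels.  The cost is honest and documented: information
about the withheld column does enter through the decomposition's
splines (though never through any forecaster's training windows), so
the reported skill should be read as skill *of the
decomposition-combination scheme*, not of a strictly causal forecaster.

**Windows** never cross gene boundaries: the concatenated series resets
sharply between genes, and boundary-crossing windows would teach the
forecasters that artificial sawtooth.  Training pairs are pooled across
genes per component; prediction reads the last L component values of a
gene's training positions and emits the next value.

**Recombination** is the plain sum of per-component predictions
(residual included by default — its slow trend carries the degradation
drift; configurable off), followed by inverse normalization.

**Per-component reports** score each forecaster against the component
values at the withheld positions of the full-series decomposition
(under `"train_only"` scope a separate full decomposition is computed
for this; component counts of the two decompositions can differ, in
which case rows are aligned by index up to the shorter list).

**Baselines.**  Last-observation persistence (the nearest observed
column) and a single LSTM trained on the raw undecomposed series under
the identical protocol.  Skill comparisons use RMSE on the normalized
scale — the scale on which the evaluation metrics are defined —
so every gene contributes comparably rather than the highest-expressed
genes dominating.

## Metrics

RMSE and R² are implemented in two variants each: the forms defined
with an (n−1) RMSE denominator and with R² as the explained-SS ratio
Σ(ŷ−ȳ)²/Σ(y−ȳ)² (the defaults, and the forms the reference results
were reported in), plus the conventional n-denominator RMSE and
1 − SS_res/SS_tot.  The explained-SS R² is *not* a goodness-of-fit
measure — permuting predictions can leave it at 1 — which is why every
report embeds `rmse_denominator` and `r2_formula` flags.  Spearman ρ
uses average ranks for ties and is undefined (NaN) for constant input.
The paired prediction-vs-truth location test defaults to a two-sided
paired t-test (Wilcoxon signed-rank selectable); all-zero differences
report p = 1.

Reference values reported for the original mouse-brain degradation
panel — reverse/0 h RMSE 0.2558, MAE 0.2105, R² 0.4771 and forward/6 h
RMSE 0.4002, MAE 0.3169, R² 0.6145 (the source's figure caption and
text disagree on which triple belongs to which direction) — depend on
that dataset and on unreported training configuration.  They are
recorded here as context only and are not test assertions; on the
synthetic panels this implementation's normalized-scale reverse RMSE
is typically ≈ 0.18–0.27.

## Synthetic data

Two generators make every stage testable without downloads.

*Tone mixtures*: sums of distinct-frequency sinusoids (optional AM,
optional additive Gaussian noise) with each noiseless component
returned — the classical EMD validation input, with a resolvability
guard (≥ 16 samples per cycle of the fastest tone).

*Degradation panels*: G = 60 genes × T = 12 time points by default,
matching the triplicate layout 0.1 h … 6.3 h.  Each gene follows
b_g · exp(−λ_g t) · (1 + A sin(2πt/P + φ_g)) · ε with log-uniform
baselines b_g ∈ [1, 1000] (FPKM scale), 70% of genes decaying at
λ_g ~ U(0.05, 0.5) h⁻¹ (exponential decay is the simplest monotone
model of RNA degradation kinetics; the rest have λ = 0), a mild shared
oscillation (A = 0.15, period P = 2 h, matching the triplicate block
spacing), and multiplicative lognormal noise ε with σ = 0.15 — a
typical replicate-level coefficient of variation for bulk RNA-seq
FPKM.  The truth record carries every drawn parameter and the
noiseless matrix, bit-reproducibly under the seed.

What the generator does *not* emulate: count-level sampling noise
(negative-binomial library-size effects), gene–gene correlation,
transcript-specific degradation kinetics beyond a single exponential,
and batch structure.  Passing tests on these panels therefore
demonstrates that the pipeline recovers the kind of structure it
assumes (smooth per-gene decay + oscillation + noise); they do not
certify performance on real RNA-seq data.

## Known limitations

- IMF counts are sensitive to the SD threshold and boundary policy;
  on real 60 × 12 panels the count lands near the dyadic expectation
  (≈ 6–9 for N = 660–720) but an exact count is not a stable property
  of the algorithm.
- The default decomposition scope trades strict causality for
  usefulness (see *Decomposition scope* above); use
  `decompose_scope="train_only"` when a strictly causal forecast is
  required, and expect persistence-level or worse accuracy at the
  gene-boundary targets.
- One-step-ahead recombination predicts a single withheld time point;
  multi-horizon joint forecasting is out of scope.
- Training is CPU-only, full-batch, single-layer; no hyperparameter
  search is attempted.
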