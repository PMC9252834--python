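# Methods

This note documents the models implemented in `synscore`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the problem was genuinely
open.

## Response scale and data model

All analysis happens on the % inhibition scale: 0 = untreated control
signal, 100 = complete inhibition of the readout. Values outside [0, 100]
(stimulation, super-inhibition) are *preserved* in the data tensor —
downstream models must see raw measurements — and clamped only where a
formula requires it (noted per operation below). A `CombinationBlock`
holds one experiment: per-drug dose vectors that always start at dose 0
and increase strictly, and an n-dimensional response tensor whose axes
carry the single-agent responses and whose all-zero-dose cell is the
control, defined 0. Replicate rows are averaged into the working tensor;
the replicate stack is retained but not otherwise used (replicate-based
significance testing is out of scope). Missing single-agent cells are
tolerated when at least 2 positive doses per drug remain; missing
combination cells are an error.

Raw-count input is normalized per block against controls. Default
orientation is a surviving-signal readout
(`response = 100·(1 − count/mean(neg))`, or the two-point form when
positive controls are given). The killed-signal orientation
(counts rise with inhibition) requires positive controls, because without
them the 100 % level is undefined.

Dose units are carried as labels only; no unit conversion happens
anywhere. Heterogeneous concentration ranges are handled by the
concentration-weighting scheme, not by unit arithmetic.

## Single-agent dose-response curves

The four-parameter log-logistic model
`y(d) = l + (u − l)/(1 + (EC50/d)^h)` is fitted by bounded nonlinear
least squares (`scipy.optimize.least_squares`, trf). Choices that matter:

- **Monotonicity** is enforced by parametrizing the span `u − l ≥ 0`;
  bounds are l ∈ [−50, 150], u − l ∈ [0, 250], h ∈ [0.05, 20], and
  log₁₀ EC50 within ±3 decades of the tested dose range.
- **Determinism**: fits start from a fixed 3×3 grid over
  EC50 ∈ {min dose, geometric mid, max dose} × h ∈ {0.5, 1, 3}; the best
  residual sum of squares wins, ties broken by smaller h then smaller
  EC50. No randomness enters the fit.
- **Zero dose** is evaluated by the closed-form limit y(0) = l, never by
  log(0).
- **Degenerate data**: an explicit flat candidate (span 0, l = mean
  response) competes with the sigmoidal starts, so constant data yields
  an exactly flat curve instead of a numerically wandering one.
- **Non-sigmoidal data** still gets a monotone fit, with a poor-fit
  warning when RSS per residual degree of freedom exceeds 100 %inh².
  Robust regression is deliberately absent — outliers are the QC module's
  job, not the fitter's.

Dose inversion is closed-form; responses at/below l signal "dose 0" and
at/above u signal "unbounded", which the Loewe solver uses to handle
saturation explicitly.

## Reference models

- **Bliss**: `100·(1 − ∏(1 − yᵢ/100))` with each yᵢ clamped to [0, 100]
  inside the product only — survival fractions outside [0, 1] are
  unphysical and destabilize higher-order products.
- **HSA**: max of the single-agent responses (no clamping; negative
  values are legitimate).
- **Loewe**: bisection on the response y of `∑ dᵢ/Dᵢ(y) = 1` over the
  open interval (maxᵢ lᵢ, minᵢ uᵢ), run to interval convergence
  (≪ the 10⁻⁶ sum tolerance). If even the top of the interval leaves the
  dose-fraction sum above 1, every curve is saturated and the expected
  effect is minᵢ uᵢ. Non-overlapping response ranges (max l ≥ min u)
  raise a degenerate-curves error.
- **ZIP** (two-drug blocks): for each row/column, the marginal
  dose-response is re-fitted with the zero-dose anchor pinned to the
  partner's fitted single-agent response; the expectation is the Bliss
  combination of the two fitted single-agent values and the delta is the
  mean of the two directional fitted-minus-expected differences. An exact
  multiplicative-survival surface therefore scores 0 identically. ZIP for
  more than two drugs is unsupported (the construction is
  directional-pairwise).

Bliss and HSA expectations use *measured* single-agent axis responses
(after any outlier correction), falling back to curve predictions only
for missing axis cells; Loewe and ZIP necessarily use fitted curves.

- **Bliss/Loewe consensus**: expected effect = pointwise max over the
  Bliss, Loewe and HSA expectations, hence delta = pointwise min of the
  three deltas — the most conservative call at every cell. For responses
  inside [0, 100] the HSA expectation can never exceed Bliss, so the max
  effectively reduces to max(Bliss, Loewe). ZIP is excluded by design
  (same multiplicative-survival principle as Bliss). Defined for any
  number of drugs. When Loewe is undefined (degenerate curves) the
  consensus is reported missing with a diagnostic rather than silently
  falling back to the remaining models.

**Summaries.** `mean_delta` averages delta over the all-positive-dose
cells only; zero-dose rows/columns are 0 by construction and would dilute
the score. The most-synergistic-area score is the maximal mean over
axis-aligned windows of edge length 3 (user-adjustable), clipped per axis
with a warning when the grid is smaller.

## Outlier QC

The QC contract is: model-based prediction per cell → deviation =
observed − predicted → flag when |deviation| > 20 %inh (strict; a tiny
1e-9 numerical guard keeps exact-boundary deviations unflagged) →
optional replacement by the prediction. Replacement is opt-in.

- **Combination cells**: each cell's prediction is a leave-one-out
  reconstruction — the cell is masked, a rank-2 non-negative matrix
  factorization (hand-written multiplicative updates with a mask; 400
  iterations) is fitted to the rest of the shifted matrix
  (responses − min, so entries are non-negative), refitted from 5 fixed
  seeds and averaged, then shifted back. Shifting by the matrix minimum
  makes the whole procedure — and hence the flag set — invariant to
  adding a constant to all responses. The reconstruction is an
  unsupervised low-rank predictor; dose-response surfaces are smooth and
  close to (constant − rank-1) structure, so rank 2 recovers clean
  interior cells to within a few %inh. For blocks of more than two drugs
  every two-drug slice is reconstructed and overlapping predictions
  averaged. Corner extrapolation on very small grids is unreliable, which
  is harmless: only all-positive-dose cells are ever flagged from this
  predictor.
- **Single-agent cells**: leave-one-out Hill refits per axis (skipped
  with a warning below 4 points including dose 0). Candidates are
  processed greedily: the point whose exclusion leaves the
  lowest-RSS refit of the remaining points is the prime suspect and is
  flagged if its own deviation from that refit exceeds the threshold,
  then permanently excluded, and the pass repeats. Ranking by raw
  deviation instead would let one gross spike contaminate the fits of its
  clean neighbours (observed in development: a +40 %inh spike produced
  apparent −60 to −78 %inh deviations at clean points).
- The absolute deviation is used (both directions are experimental
  errors), and corrections are applied before *all* downstream scoring:
  single-agent QC first (so corrected axes feed the combination
  reconstruction and the Bliss/HSA expectations), then combination QC.

A consensus summary score strictly below −5 marks the block
low-confidence in the pipeline output (strict: −5.0 itself is not
flagged).

## Concentration weighting

Each all-positive-dose cell gets weight
`√(∏ₙ (100 − yₙ)/(100 − lₙ))`, with yₙ the *measured*
(outlier-corrected) single-agent response of drug n at its dose in the
cell and lₙ the fitted lower asymptote. Each factor is clamped to [0, 1]
before the product: the raw expression is over-unity for y < l and
negative for y > 100, and the weight's role is purely to down-weight
high-effective-dose cells. A lower asymptote within 1e-9 of 100 %inh is a
degenerate-curve error (division by ~0). The weighted summary is the
plain mean of weight × delta over positive cells, deliberately *not*
renormalized by the mean weight — a block whose weights are uniformly 0.5
genuinely deserves half the score, since its synergy sits at high
effective doses.

## MuSyC decomposition

The two-drug surface model is the steady state of the four-state
mass-action system (unaffected U, singly affected A₁/A₂, doubly affected
A₁₂) with unit reverse rates and forward weights (d₁/C₁)^h₁, (d₂/C₂)^h₂,
and α-scaled versions for the second binding step; cooperativity
interaction (gamma) is fixed at 1, outside this package's scope. The
steady state is obtained per dose pair as a batched 4×4 linear solve —
exact, vectorized and robust to extreme dose/potency ratios — rather than
a transcribed closed form. At α₁₂ = α₂₁ = 1 the two processes decouple
into the independence product (the no-interaction null of the family).

Effects are modeled on the normalized inhibition scale (E0 ≈ 0 baseline,
E/100); the combination maximum is parametrized as
E3 = max(E1, E2) + β, so β is directly the efficacy gain over the
stronger single agent. Fitting is bounded least squares with single-agent
Hill fits seeding E/C/h and a deterministic 3×3 multi-start over
α ∈ {0.1, 1, 10}²; log-α bounds are ±2. Non-sigmoidal monotherapies
attach a quality warning to the fit (the model assumes monotone sigmoidal
single agents) but do not abort it.

Mode labels use the geometric-mean α on the log₁₀ scale against a 0.1
tolerance (potency axis) and β against 0.05 (efficacy axis); these
tolerances are configurable analysis defaults, not published constants.
The label lattice maps same-direction synergy on both axes to `both`,
single-axis calls to the four potency/efficacy (synergy/antagonism)
labels, and any other two-axis combination — opposite signs *or* double
antagonism — to `mixed`, since the label set has no dedicated
double-antagonism term.

## Multi-sample analysis

Every block is scored independently (no cross-block information flows),
so batch results equal per-block runs cell-by-cell and input order cannot
affect any export (everything is sorted). Combination identity is the
sorted drug-name tuple; blocks testing (A, B) and (B, A) in the same
sample are averaged with a warning. A block that fails to score becomes
an explicit missing cell with its diagnostic — never 0 — and only a batch
with zero scorable blocks errors out. Consistency statistics per
combination are n, mean, sd (missing below 2 samples), min, max and the
fraction of samples with positive score; these are pragmatic defaults,
not field-standard definitions.

## Synthetic data generator

`simulate_block` builds single agents from exact Hill curves, fills
combination cells from the chosen null (Bliss/HSA/Loewe of the noiseless
single-agent values, or a MuSyC surface with chosen α/β), adds an
injected synergy delta to the all-positive-dose cells, then Gaussian read
noise (the control cell stays 0), then point outlier shifts. The seed
fully determines the output, and every noiseless intermediate is returned
as ground truth. Multi-sample simulation jitters each drug's EC50
log-normally (sd = jitter, in log units) and its upper asymptote by
N(0, 10·jitter) %inh per sample, with per-sample seeds derived from the
master seed.

What it emulates: plate-reader read noise (Gaussian on the %inh scale,
the standard first-order model), sporadic gross measurement errors
(point shifts), and between-sample biological variability (potency and
efficacy jitter). What it does not: spatial plate effects (edge drift,
gradients), correlated noise, assay-specific error-variance structure,
or biphasic pharmacology. Passing tests therefore demonstrate
correctness of the scoring machinery and robustness to independent noise
and point outliers — not robustness to structured artefacts of any
particular assay chemistry.

Default study conditions used across tests and the acceptance script:
6-point dose grids (0 plus five half-log-spaced doses) for scoring and QC
checks, 8-point grids for MuSyC; read noise sd 2–3 %inh; outlier spikes
±30 %inh; 50 blocks for the QC recovery experiment and 100 curves for
EC50 recovery; Hill parameters in realistic screening ranges
(l ≈ 0–10, u ≈ 60–100 %inh, EC50 log-uniform over the dose range,
h ≈ 0.5–4).

## Known limitations

- The combination-outlier predictor is an unsupervised low-rank
  reconstruction; it flags deviations from smooth surface structure and
  cannot use cross-experiment information the way a predictor trained on
  a large screening corpus could.
- Loewe (and hence the consensus) is undefined for flat or
  non-overlapping monotherapy curves; such blocks report missing values
  with diagnostics.
- ZIP and MuSyC are two-drug only; the consensus and the remaining
  models support any order.
- No replicate-level statistics or confidence intervals on synergy
  scores; no interactive visualization (plot-ready tables are exported
  instead).
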