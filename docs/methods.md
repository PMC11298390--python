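# Methods

## Problem and data

`scfsol` correlates the mole-fraction solubility *y* of a poorly
water-soluble drug (ketoprofen) in supercritical CO₂ with temperature
*T* [K] and pressure *P* [bar].  The bundled dataset is a 4 × 7 factorial
grid — T ∈ {308.15, 318.15, 328.15, 338.15} K, P ∈ {160, …, 400} bar,
28 records — with solubility spanning 2.21 × 10⁻⁵ to 7.12 × 10⁻⁴.
Solubility is treated as a dimensionless mole fraction and is never
transformed before modeling; only the (T, P) features are standardized
(zero mean, unit variance on the training data).  Error magnitudes in all
reports are therefore on the raw solubility scale (MSE ~ 10⁻⁹).

## Model families

All three families regress *y* on standardized (T, P) and are implemented
as scikit-learn estimators wrapped in a `StandardScaler` pipeline.

**Piecewise polynomial regression (PPR).**  A binary tree of axis-aligned
splits partitions the (T, P) box, CART-style; each leaf carries an
independent ordinary-least-squares polynomial of total degree *d* ∈ {1,2,3}.
Splits are candidate midpoints between sorted unique training coordinates
and are accepted greedily while they decrease the penalized criterion
RSS + *w*·(number of coefficients), subject to `max_segments` and to every
leaf holding at least as many points as its polynomial has coefficients.
No continuity is imposed at segment boundaries (the CART framing implies
none).  Tie-breaks are deterministic: earlier axis (T before P), then lower
threshold.  Points on a boundary route to the upper/right child; queries
outside the box simply follow the threshold tests, i.e. use the nearest
boundary leaf.  A relative improvement floor (10⁻¹⁰ of the target's total
sum of squares) keeps float-level RSS noise on exactly polynomial data from
triggering spurious splits.  Complexity for AIC: leaves × monomials.

**Kernel ridge regression (KRR).**  Penalized least squares in the RKHS of
the Gaussian kernel k(x, x′) = exp(−γ‖x − x′‖²), objective
(1/N)Σ(f(xᵢ) − yᵢ)² + λ‖f‖²_H.  The representer theorem reduces this to the
dual system (K + λN·I)α = y, solved by Cholesky factorization.  Complexity
for AIC is the effective degrees of freedom tr[K(K + λN·I)⁻¹].  λ and γ are
tuned on a log scale over [10⁻¹⁰, 1] and [10⁻³, 10²].

**Tweedie GLM (TDR).**  Y ~ Tweedie(μ, φ) with Var(Y) = φ·μᵖ, log link,
linear predictor in standardized (T, P).  Fitting is quasi-likelihood IRLS
(working weights μ^{2−p} under the log link), converged at relative
coefficient change < 10⁻¹⁰ or 100 iterations; φ is the mean squared Pearson
residual over (n − #coefficients).  The power is tuned continuously in
[1.1, 2.0] (p = 2 is the gamma GLM; p ≤ 1 and p > 2 are irrelevant to
strictly positive solubility).  An optional ridge term (intercept excluded)
stabilizes the working normal equations and is tuned on a log scale.
Exact Tweedie densities are never evaluated.  Complexity for AIC:
coefficients + 1 for φ.

## Water cycle algorithm

Hyperparameters are tuned by a canonical single-objective water cycle
algorithm.  The population is ranked by cost: best = sea, next
N_sr − 1 = rivers, rest = streams, allocated to sea/rivers proportionally to
cost-derived intensity.  Flow: X_new = X + U(0, 2)(X_target − X).  A mover
that beats its target swaps roles, so the sea is always the incumbent best
(elitism; the best-cost history is non-increasing by construction).
Evaporation: rivers (and sea-assigned streams) within d_max of the sea are
re-sampled uniformly; d_max ← d_max − d_max/max_iterations, i.e. it decays
to d₀(1 − 1/M)^M ≈ d₀/e over a run.  The search space is handled on the
unit cube — log axes flow in log space, integers are repaired by rounding,
categoricals by nearest index, out-of-bounds moves are clipped.

Optimizer defaults (population 30, N_sr 4, d_max 0.1, 200 iterations) suit
cheap objectives; the *pipeline* default budget is population 16,
30 iterations, because each objective call there costs five model fits and
the study loops over ten split seeds and three families.  These sizes are
the package's choice; raising them changes the headline numbers only
marginally (the budget-monotonicity test checks more iterations are never
worse in median).

## Tuning protocol and evaluation

For each family: 80/20 random split (test size = round-half-up of 0.2·n);
the WCA minimizes the pooled RMSE of 5-fold cross-validation predictions on
the training subset (plain training RMSE would reward interpolation);
then the top 5 distinct candidates of the final population, plus the best
solution ever seen, are refit on the full training subset and the one with
the least AIC = n·ln(MSE) + 2k is kept.  Failed fits cost +∞.  Metrics
(R², MSE, MAE per the usual definitions) are reported on the held-out rows,
with whole-dataset R² as a side column.

Because the original study's split seed and optimizer settings are
unreported, the headline protocol is: run the pipeline on split seeds 0–9
and report the best and the median per family.  Every random element
derives from a single base seed via `numpy.random.SeedSequence`, so two
runs of the same configuration are identical.

## Synthetic data generator

The generator emulates the structure of the real data, not its physics:

    y(T, P) = base · (1 + c·(P − P₀)) · exp(k·(T − T₀)) · exp(ε),  ε ~ N(0, σ²)

— linear in pressure, exponential in temperature, multiplicative lognormal
noise (preserves positivity and right-skew).  Defaults
(base = 1.6 × 10⁻⁵, k = 0.082 /K, c = 0.0112 /bar, (T₀, P₀) = grid minimum,
σ = 0.05) come from a one-time log-scale least-squares fit to the bundled
grid; the noiseless default surface explains > 97 % of the real data's
variance.  An optional log-scale T·P interaction coefficient exists and
defaults to zero.  `recover_params` inverts the generator by nonlinear
least squares on the log scale and is exact on noiseless data.

What passing synthetic tests do **not** show: the generator has no
density-driven crossover pressures, no heteroscedastic measurement error,
and no T–P interaction by default, so success on it demonstrates pipeline
correctness, not thermodynamic validity on new drugs.

Note on family capacity: the Tweedie log link is linear in P while the
generator surface's log is concave in P, so TDR cannot represent the
surface exactly even without noise (it reaches R² ≈ 0.985 on the noiseless
grid, against ≥ 0.99 for PPR and KRR).

## Numerical choices and degenerate inputs

- KRR with λ → 0⁺ approaches interpolation; the Cholesky solve has a plain
  solve fallback (unreachable for λ > 0, guarded anyway).
- IRLS raises with its iteration trace if working quantities go non-finite;
  linear predictors are clipped at ±690 before exponentiation.
- Zero-variance observations make R² undefined: it is returned as NaN with
  a warning, while MSE/MAE are still computed.
- Constant features cannot be standardized and are rejected.
- AIC uses max(MSE, 10⁻³⁰⁰) inside the log.
- Test sizes use round-half-up, so n = 28, fraction 0.2 gives |test| = 6.

## Known limitations

- 28 observations make held-out metrics (6 points) extremely
  split-dependent; that is why best *and* median over documented seeds are
  reported rather than one split.
- A best-of-ten-seeds R² is upward-biased relative to any single unreported
  split, so comparisons with single-split literature values are indicative
  only; our median Tweedie R² (~0.92) exceeds some published single-split
  values for the same family.
- The kernel ridge family, tuned by cross-validation and AIC-filtered, is
  as strong as or stronger than the piecewise family on this dataset in
  median; rankings among well-tuned families on 22 training rows are not
  stable study-to-study.
- No uncertainty quantification on predictions; the pipeline is a
  correlation tool, not a thermodynamic model (no Chrastil-type density
  terms).
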