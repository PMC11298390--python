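# scfsol

Regression modeling of drug solubility in supercritical CO₂.

Solubility of poorly water-soluble drugs in supercritical carbon dioxide
governs green micronization/nanonization process design.  `scfsol`
correlates mole-fraction solubility *y* with temperature *T* [K] and
pressure *P* [bar] on a small factorial grid (the bundled dataset is the
28-point ketoprofen table, 308.15–338.15 K × 160–400 bar), for process
engineers and modelers who need a reproducible, tuned correlation rather
than a thermodynamic equation of state.

Three regression families are implemented as scikit-learn estimators:

- **PPR** — piecewise polynomial regression: a CART-style tree of
  axis-aligned splits with an independent degree-*d* polynomial per leaf,
  grown under the penalized criterion RSS + *w*·#coefficients;
- **KRR** — Gaussian-kernel ridge regression, the minimizer of
  (1/N)Σ(f(xᵢ) − yᵢ)² + λ‖f‖²_H solved in the dual, (K + λN·I)α = y;
- **TDR** — a Tweedie GLM with log link and power variance
  Var(Y) = φ·μᵖ, fitted by quasi-likelihood IRLS.

Hyperparameters are tuned by a **water cycle algorithm** (WCA): a
population metaheuristic in which candidate solutions flow toward better
ones (streams → rivers → sea) and near-duplicates of the best solution
evaporate and rain back as fresh random samples.  The tuning objective is
5-fold cross-validated RMSE on the training subset; the final candidates
are filtered by AIC = n·ln(MSE) + 2k to guard against overfitting.  Models
are compared by held-out R², MSE and MAE on random 80/20 splits.

See `docs/methods.md` for the full model and protocol description.

## Worked example

```python
import scfsol
from scfsol import evaluation as ev

ds = scfsol.load_dataset("bundled")          # 28 records, 4 T x 7 P levels
result = ev.run_pipeline(ds, ev.PipelineConfig(), split_seed=0)
print(result.comparison)
```

prints (abridged):

```
  family        r2           mse       mae    r2_all
0    KRR  0.978103  1.285936e-09  0.000020  0.991443
1    PPR  0.970545  1.729841e-09  0.000028  0.990381
2    TDR  0.917975  4.817153e-09  0.000039  0.952082
```

Each row is one family's tuned model evaluated on the 6 held-out records
of split seed 0: `r2` is the coefficient of determination (1 is perfect),
`mse`/`mae` are on the raw mole-fraction scale (errors of a few 10⁻⁵ against
solubilities up to 7 × 10⁻⁴), and `r2_all` is the same model scored on all
28 records.  Because six test points make metrics very split-dependent, the
full study (`ev.run_study`) repeats this over split seeds 0–9 and reports
the best and median per family.

The trends the models should capture are in the data itself:

```python
print(ev.trend_analysis(ds, "P").r2.min())   # 0.9376  — y linear in P per T
print(ev.trend_analysis(ds, "T").r2.min())   # 0.9489  — ln y linear in T per P
```

A synthetic-surface generator (`scfsol.generate_dataset`) produces
datasets with the same structure — exponential in T, linear in P, strictly
positive with right-skewed lognormal noise — for pipeline testing and
parameter-recovery checks.

There is also a CLI: `scfsol run | simulate | predict | report`.

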