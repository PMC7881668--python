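# kwlpr — kernel-weighted local polynomial regression for QSAR/QSAAR modeling

`kwlpr` builds quantitative structure–activity (QSAR) and interspecies
structure–activity–activity (QSAAR) regression models with a kernel-weighted
local polynomial estimator instead of a single global equation. It is aimed
at computational toxicologists and cheminformaticians who have a compound
table — an endpoint such as pLC50 plus a few molecular descriptors and/or a
lower-species potency — and want a flexible nonparametric model together
with the full validation dossier regulators expect: internal and external
predictivity metrics, an applicability-domain analysis, a Y-scrambling
robustness test, and PCA-based interpretation aids.

## The estimator

For a query point $x_0$ the unknown regression function $m(x)$ is
approximated by a degree-$p$ polynomial fitted by weighted least squares,

$$\min_{\beta}\;\sum_{i=1}^{n}\Big\{y_i-\sum_{j=0}^{p}\beta_j (x_i-x_0)^j\Big\}^2\,K\!\Big(\frac{x_i-x_0}{h}\Big),$$

whose closed-form solution is $\hat\beta=(X^TWX)^{-1}X^TWy$ with
$W=\mathrm{diag}\{K((x_i-x_0)/h)\}$; the prediction is the local intercept
$\hat\beta_0$. Two degrees are supported: $p=0$, the local-constant
(Nadaraya–Watson) estimator `lc`, and $p=1$, the local-linear estimator
`ll`. With several descriptors the weight is an independent product kernel
$w_i=\prod_j K\big((x_{ij}-x_{0j})/h_j\big)$ with one bandwidth per
descriptor, evaluated on auto-scaled (zero-mean, unit-variance) variables.
Kernels: Gaussian, Epanechnikov, uniform (plus triangular and biweight).
Bandwidths are chosen by least-squares cross-validation (`cv.ls`), an
AICc-type expected Kullback–Leibler criterion (`cv.aic`), or — for one
descriptor with `ll` — the deterministic direct plug-in rule.

Model quality is reported as the standard panel: $R^2$ and RMSE$_C$
(calibration), $Q^2_{LOO}$ and RMSE$_{CV}$ (leave-one-out), $Q^2_{F1}$,
$Q^2_{F2}$, $Q^2_{F3}$, Lin's CCC, RMSE$_P$ and MAE (external validation).
The applicability domain follows the Williams-plot convention: leverage
$h_i=u_i^T(U^TU)^{-1}u_i$ against standardized residuals, with critical
leverage $h^\*=3(d+1)/n$ and a ±3 residual band.

## Worked example

```bash
# make a synthetic two-descriptor QSAAR-style table (254 train / 64 validation)
kwlpr fixtures --spec qsaar2d --n 254 --n-valid 64 --seed 1 --out qsaar.csv

# run the full modeling grid: {lc,ll} x {cv.ls,cv.aic} x {gaussian,epanechnikov,uniform}
kwlpr run --input qsaar.csv --outdir out --seed 1 --yscramble 100
```

`out/summary.csv` gets one row per combination. For the
local-constant/Gaussian/`cv.ls` model the library API gives the same
numbers:

```python
from kwlpr import KwlprModel, read_dataset, select_bandwidth, fit_scaler, validate

ds = read_dataset("qsaar.csv")
scaler = fit_scaler(ds)
sel = select_bandwidth("cv.ls", scaler.transform(ds.X_train), ds.y_train,
                       degree=0, kernel="gaussian", seed=1)
model = KwlprModel.fit(ds, degree=0, kernel="gaussian", bandwidths=sel.selected)
print(validate(model, ds).to_dict(ndigits=2))
```

```
{'r2': 0.89, 'rmse_c': 0.58, 'q2_loo': 0.85, 'rmse_cv': 0.67,
 'q2_f1': 0.87, 'q2_f2': 0.87, 'q2_f3': 0.87, 'ccc': 0.93,
 'rmse_p': 0.62, 'mae': 0.5, 'n_train': 254, 'n_valid': 64}
```

Reading: the model explains 89% of the calibration variance with a
calibration error of 0.58 log units; leave-one-out predictivity barely
drops (Q²_LOO = 0.85), the external set is predicted with Q²_F1/F2/F3 ≈
0.87 and a concordance of 0.93, and the prediction error (0.62) stays close
to the calibration error — no sign of overfitting. With d = 2 descriptors
and 254 training compounds the critical leverage is h* = 9/254 ≈ 0.035;
`kwlpr.williams_table` flags compounds beyond it as X-outliers and
|standardized residual| > 3 as Y-outliers. A 100-fold Y-scrambling run on a
genuine model yields permuted R² far below the true value (empirical
p < 0.05), confirming the relationship is not a chance correlation.

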