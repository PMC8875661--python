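"""Fit and validate a pp-LFER model on a synthetic 41-compound cohort.

Generates descriptors and endpoints under the default study conditions
(noise targeting R² ≈ 0.9), splits 4:1, fits the aqueous logK model on
the Abraham descriptors (E, S, A, B, V) and prints the full validation
suite: the closer R²_adj/Q² values are to 1, the better the fit,
robustness and external predictivity.
"""

from nanosorb.lfer import fit_pplfer, split_train_validation, validate, williams_domain
from nanosorb.synthetic import GeneratorConfig, generate_descriptor_table, generate_endpoints

config = GeneratorConfig()  # 41 compounds, reference-model truth
table = generate_descriptor_table(config, seed=0)
dataset = generate_endpoints(table, config, seed=1)
train, valid = split_train_validation(dataset.table, seed=2)

model = fit_pplfer(train, "logK_aqueous")
print("logK_aqueous =", f"{model.intercept:.2f}",
      " ".join(f"{c:+.2f}·{d}" for d, c in model.coefficients.items()))

report = validate(train, valid, "logK_aqueous", k=5, repetitions=1000, seed=3)
print(f"n_train={report.n_train}  n_ext={report.n_ext}")
print(f"R2_adj={report.r2_adj:.2f}  RMSE_tra={report.rmse_train:.2f}")
print(f"Q2_LOO={report.q2_loo:.2f}  Q2_kfold={report.q2_kfold:.2f}")
print(f"Q2_ext={report.q2_ext:.2f}  RMSE_ext={report.rmse_ext:.2f}")

ad = williams_domain(model, train, valid)
print(f"leverage threshold h* = {ad.leverage_threshold:.3f}; "
      f"{int((~ad.train.in_domain).sum())} training compounds out of domain")
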