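"""Evaluate a fitted response model: DeLong AUC and test, threshold metrics,
Hosmer-Lemeshow calibration, decision curve, Shapley attribution, nomogram.
"""

import numpy as np
import pandas as pd

import habitatbm as hb

rng = np.random.default_rng(0)
n = 600
n_train = 400
X = pd.DataFrame(rng.standard_normal((n, 4)), columns=["rad_score", "pni", "gender", "noise"])
eta = 1.6 * X.rad_score + 0.6 * X.pni - 0.5 * X.gender
y = rng.binomial(1, 1 / (1 + np.exp(-eta)))

spec = hb.SignatureSpec("combined", list(X.columns))
model = hb.train_model(X.iloc[:n_train], y[:n_train], spec, algorithm="LR", cv_folds=5, seed=0)
scores_val = hb.predict(model, X.iloc[n_train:])
y_val = y[n_train:]

report = hb.evaluate_model(scores_val, y_val,
                           threshold=hb.youden_threshold(model.training_predictions, y[:n_train]))
print("validation AUC %.3f (95%% CI %.3f-%.3f)" % (report.auc, *report.ci))
print("sens %.3f spec %.3f PPV %.3f NPV %.3f acc %.3f (training-frozen threshold)" % (
    report.metrics["sensitivity"], report.metrics["specificity"],
    report.metrics["ppv"], report.metrics["npv"], report.metrics["accuracy"]))
print("Hosmer-Lemeshow chi2 %.2f, p %.3f (high p = no evidence of miscalibration)"
      % (report.hl_statistic, report.hl_p))

noise_scores = rng.uniform(size=len(y_val))
z, p = hb.delong_test(scores_val, noise_scores, y_val)
print("DeLong test vs a noise model: z %.2f, p %.2e" % (z, p))

nb = report.dca
best = nb.loc[nb.threshold.sub(0.3).abs().idxmin()]
print("net benefit at threshold 0.30: model %.3f vs treat-all %.3f"
      % (best.net_benefit, best.treat_all))

shap = hb.shapley_attribution(model, X.iloc[n_train:n_train + 20], X.iloc[:100])
print("global |contribution| ranking:",
      {k: round(v, 3) for k, v in shap.global_ranking().items()})

nomo = hb.nomogram_export(model, {c: (X[c].min(), X[c].max()) for c in X.columns})
row = X.iloc[450]
print("nomogram: %.1f points -> probability %.3f (model says %.3f)" % (
    nomo.points(row), nomo.probability(row), hb.predict(model, X.iloc[[450]])[0]))
# The nomogram reproduces the logistic model exactly; the largest
# single-predictor span is scaled to 100 points.
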