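"""Prediction accuracy: two-step OLS vs Bayesian fits under masking.

Simulates a kinship-structured trial, repeatedly hides one environment
per line, refits each method on the masked data and correlates
predictions with the held-back records.  OLS fits the training data best
but predicts masked records worst; shrinkage and kinship reverse the
ordering out of sample.
"""

from fwreg import (
    GibbsConfig,
    crossvalidate,
    fit_ols,
    run_gibbs,
    simulate_fw_table,
    simulate_kinship,
)

A = simulate_kinship(n_lines=100, n_markers=1000, seed=11, n_families=10)
table, _ = simulate_fw_table(
    n_lines=100, n_envs=4, var_e=0.3, var_g=0.09, var_b=0.10, var_h=0.9,
    A=A, seed=12,
)

cfg = dict(n_iter=2500, burn_in=500)
fitters = {
    "OLS": fit_ols,
    "Gibbs (A=I)": lambda t: run_gibbs(t, config=GibbsConfig(seed=1, **cfg))[0],
    "Gibbs (A=G)": lambda t: run_gibbs(t, A=A, config=GibbsConfig(seed=1, **cfg))[0],
}
report = crossvalidate(table, fitters, n_replicates=5, seed=13)
means = report.groupby("method", sort=False)[["cor_train", "cor_validation"]].mean()

print("mean correlation over 5 masked partitions:")
print(means.round(3).to_string())
print("\ncor_train: fitted vs observed on records the model saw (OLS wins by"
      "\noverfitting); cor_validation: predictions for the hidden records"
      "\n(the Bayesian fits win, and kinship helps further).")
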