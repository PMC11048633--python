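"""Test the normal-copula assumption on a fitted model.

D_E is the determinant of the data's Spearman rank correlation matrix
(1 = total independence, 0 = exact linear dependence).  Resampling the
fitted joint law at the same sample size gives the reference distribution
of D_N; if D_E sits inside its central 90% band the copula assumption
cannot be rejected at the 10% level.
"""

from wetlandnbn import default_ground_truth, fit_nbn, generate, validate_model

truth = default_ground_truth()
table = generate(truth, 16, seed=42)
nbn = fit_nbn(table, truth.dag)

report = validate_model(nbn, table, n_replicates=4000, seed=1)
print(f"D_E                    = {report.D_E:.3e}")
print(f"90% band of D_N        = [{report.q05:.3e}, {report.q95:.3e}]")
print(f"D_E quantile position  = {report.D_E_quantile:.2f}")
verdict = "not rejected at the 10% level" if report.passed else "REJECTED"
print(f"normal copula          : {verdict}")
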