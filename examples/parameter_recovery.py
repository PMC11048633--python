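"""Parameter recovery from synthetic data with a known copula structure.

At n = 10^4 rows the fitted arc correlations are essentially unbiased
(max |bias| well under 0.01).  At the study scale of n = 16 wetlands the
same estimates carry large finite-sample noise (arc RMSE up to ~0.6 for
arcs conditioned on many earlier parents) — the price of a 16-site design,
worth keeping in mind when reading any n = 16 fit.
"""

from wetlandnbn import default_ground_truth, recovery_report

truth = default_ground_truth()

rep = recovery_report(truth, 10_000, n_trials=20, seed=2025)
print("recovery at n = 10,000 (20 trials):")
print(rep["arcs"][["parent", "child", "true", "bias", "rmse"]].to_string(
    index=False, float_format=lambda v: f"{v:+.3f}"))
print(f"max |bias| = {rep['max_abs_arc_bias']:.4f}")

rep16 = recovery_report(truth, 16, n_trials=50, seed=7)
print(f"\nrecovery at n = 16 (50 trials): max arc RMSE = {rep16['max_arc_rmse']:.2f}")
print("finite-sample uncertainty at the study scale is substantial;")
print("arc signs, not magnitudes, are the robust read-out at n = 16.")
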