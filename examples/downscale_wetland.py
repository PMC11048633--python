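"""Downscale the regional model to one wetland: pin the wetland's traits as
evidence (Bayesian conditionalization) and predict its species count, then
replay the shipped single-wetland scenario suite.

The shipped local suite encodes a hydrologically stressed coastal wetland
(fluctuations 6.8 cm, no salinity, scattered diversions and discharges,
localized tourism) with worst-case, best-case and mixed overrides.
"""

import warnings

from wetlandnbn import default_ground_truth, local_scenarios, run_local, run_suite

warnings.filterwarnings("ignore", message=".*outside observed support.*")

nbn = default_ground_truth().exact_nbn(n_reference=2000, seed=3)
specs = local_scenarios()

base = run_local(nbn, specs[0], n_samples=100_000, seed=20160701)
print(f"baseline prediction for the wetland: {base.species_int} species "
      f"(unrounded {base.mean:.1f})")

suite = run_suite(nbn, specs, n_samples=100_000, seed=20160701)
cols = ["id", "species_int", "delta"]
print("\nspecies count under each local scenario:")
print(suite[cols].to_string(index=False, float_format=lambda v: f"{v:5.1f}"))
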