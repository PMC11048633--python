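"""What-if scenario engine: baseline, worst-case, best-case and mixed
conditionings at two scales.

Regional scenarios condition *only* the scenario variables and leave every
other trait distributed as fitted, answering "what happens to the wetland
population if X changed everywhere, all else being equal".  Local
scenarios pin *all* of a wetland's listed traits at their observed values
and apply the scenario overrides on top, answering "what happens to this
wetland".  Regional results are a mean +/- SD over the wetland population;
local results are additionally rounded to an integer species count for
report tables (the unrounded mean is retained).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .copula import FittedNBN, predict_target
from .exceptions import ScenarioError, SchemaError
from .io import ScenarioSpec

__all__ = ["ScenarioResult", "run_regional", "run_local", "run_suite", "lever_ranking"]

DEFAULT_N_SAMPLES = 100_000
DEFAULT_SEED = 20160701


@dataclass
class ScenarioResult:
    id: str
    scope: str
    evidence: dict
    mean: float
    sd: float
    species_int: int
    delta: float = 0.0
    delta_pct: float = 0.0
    n_samples: int = DEFAULT_N_SAMPLES
    seed: int = DEFAULT_SEED

    def to_dict(self) -> dict:
        return asdict(self)


def _run(nbn: FittedNBN, spec: ScenarioSpec, evidence: dict, n_samples: int, seed: int):
    spec.validate_against(nbn.dag)
    mean, sd = predict_target(nbn, evidence, n_samples=n_samples, seed=seed)
    return ScenarioResult(
        id=spec.id,
        scope=spec.scope,
        evidence=dict(evidence),
        mean=mean,
        sd=sd,
        species_int=int(round(mean)),
        n_samples=int(n_samples),
        seed=seed,
    )


def run_regional(
    nbn: FittedNBN,
    spec: ScenarioSpec,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = DEFAULT_SEED,
) -> ScenarioResult:
    """Regional conditionalization: only the scenario variables are fixed."""
    if spec.scope != "regional":
        raise ScenarioError(f"scenario {spec.id} has scope {spec.scope!r}, not regional")
    return _run(nbn, spec, spec.evidence, n_samples, seed)


def run_local(
    nbn: FittedNBN,
    spec: ScenarioSpec,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = DEFAULT_SEED,
) -> ScenarioResult:
    """Local (single-wetland) conditionalization: the wetland's baseline
    trait values with the scenario overrides merged on top."""
    if spec.scope != "local":
        raise ScenarioError(f"scenario {spec.id} has scope {spec.scope!r}, not local")
    if not spec.baseline and not spec.evidence:
        raise ScenarioError(
            f"local scenario {spec.id} carries no baseline evidence"
        )
    return _run(nbn, spec, spec.full_evidence(), n_samples, seed)


def run_suite(
    nbn: FittedNBN,
    specs: list[ScenarioSpec],
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Run a scenario list and report deltas against the baseline.

    The baseline row (the scenario with no overrides, e.g. S_0) is placed
    first; absolute and percent deltas are computed against it within the
    suite's scope.
    """
    if not specs:
        raise ScenarioError("empty scenario list")
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise SchemaError(f"duplicate scenario ids in suite: {sorted(ids)}")
    results = []
    for spec in specs:
        runner = run_regional if spec.scope == "regional" else run_local
        results.append(runner(nbn, spec, n_samples=n_samples, seed=seed))

    baselines = [r for r, s in zip(results, specs) if not s.evidence]
    if not baselines:
        raise ScenarioError("suite has no baseline scenario (empty override map)")
    base = baselines[0]
    ordered = [base] + [r for r in results if r is not base]
    for r in ordered:
        r.delta = r.mean - base.mean
        r.delta_pct = 100.0 * r.delta / base.mean if base.mean != 0 else float("nan")
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "scope": r.scope,
                "evidence": json.dumps(r.evidence, sort_keys=True),
                "mean": r.mean,
                "sd": r.sd,
                "species_int": r.species_int,
                "delta": r.delta,
                "delta_pct": r.delta_pct,
                "n_samples": r.n_samples,
                "seed": r.seed,
            }
            for r in ordered
        ]
    )


def lever_ranking(suite: pd.DataFrame, specs: list[ScenarioSpec]) -> pd.DataFrame:
    """Rank single-variable scenarios by |delta|: which trait is the
    strongest management lever."""
    single = {s.id: next(iter(s.evidence)) for s in specs if len(s.evidence) == 1}
    sub = suite[suite["id"].isin(single)].copy()
    sub["variable"] = sub["id"].map(single)
    sub["abs_delta"] = sub["delta"].abs()
    sub = sub.sort_values("abs_delta", ascending=False, kind="mergesort")
    return sub[["id", "variable", "mean", "delta", "abs_delta"]].reset_index(drop=True)
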