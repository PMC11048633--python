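"""Input handling: wetland trait tables, metamodel DAG configs, scenario files.

The analysis unit is the wetland.  A trait table holds one row per wetland
with three spatial traits (size, isolation, distance to the coastline), two
anthropic traits and five hydrological traits, plus the observed alpha avian
diversity (number of waterbird species).  Five traits are scored on an
ordinal severity scale 0-3 (0 = absent, 1 = localized, 2 = scattered,
3 = widespread).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .exceptions import GraphError, ScenarioError, SchemaError, TableValueError

logger = logging.getLogger(__name__)

ID_COLUMN = "wetland_id"
SINK = "alpha_diversity"

#: ordinal severity traits, scored in {0, 1, 2, 3}
ORDINAL_TRAITS = (
    "tourism_pressure",
    "anthropization",
    "water_salinity",
    "water_discharges",
    "water_diversions",
)

#: continuous (or score-valued) traits with their lower bounds
CONTINUOUS_TRAITS = (
    "size",
    "isolation",
    "distance_to_coastline",
    "mean_water_level",
    "water_level_fluctuations",
)

TRAIT_COLUMNS = CONTINUOUS_TRAITS + ORDINAL_TRAITS

#: canonical column order for trait tables
SCHEMA_COLUMNS = (ID_COLUMN,) + TRAIT_COLUMNS + (SINK,)

ORDINAL_LEVELS = (0, 1, 2, 3)


@dataclass
class TraitTable:
    """A validated wetland trait table.

    ``data`` is a DataFrame with the canonical column order; ``wetland_id``
    is kept as a regular column.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = validate_trait_table(self.data)

    @property
    def n_wetlands(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def row_evidence(self, wetland_id: str, variables=None) -> dict:
        """Trait values of one wetland as an evidence map (sink excluded)."""
        rows = self.data[self.data[ID_COLUMN] == wetland_id]
        if rows.empty:
            raise SchemaError(f"unknown wetland_id {wetland_id!r}")
        row = rows.iloc[0]
        variables = TRAIT_COLUMNS if variables is None else variables
        return {v: float(row[v]) for v in variables}

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the schema and return the table with columns in canonical order.

    Validation is idempotent: re-validating a valid table is a no-op.
    """
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(SCHEMA_COLUMNS)].reset_index(drop=True)
    if len(df) < 3:
        raise SchemaError(f"trait table needs at least 3 wetlands, got {len(df)}")
    if df[ID_COLUMN].duplicated().any():
        dupes = df.loc[df[ID_COLUMN].duplicated(), ID_COLUMN].tolist()
        raise SchemaError(f"duplicate wetland_id(s): {dupes}")

    numeric = df.drop(columns=[ID_COLUMN])
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise TableValueError(f"missing values in column(s): {bad}")

    for col in ORDINAL_TRAITS:
        values = df[col].to_numpy()
        ok = np.isin(values, ORDINAL_LEVELS)
        if not ok.all():
            row = df.loc[~ok, ID_COLUMN].iloc[0]
            raise TableValueError(
                f"{col} must be in {set(ORDINAL_LEVELS)}; "
                f"offending wetland_id {row!r}"
            )
        df[col] = values.astype(int)

    checks = [
        ("size", df["size"] > 0, "must be > 0 (hectares)"),
        ("distance_to_coastline", df["distance_to_coastline"] >= 0, "must be >= 0"),
        ("mean_water_level", df["mean_water_level"] >= 0, "must be >= 0 (cm)"),
        (
            "water_level_fluctuations",
            df["water_level_fluctuations"] >= 0,
            "must be >= 0 (cm)",
        ),
        (SINK, df[SINK] >= 0, "must be a non-negative species count"),
    ]
    for col, ok, msg in checks:
        if not ok.all():
            row = df.loc[~ok, ID_COLUMN].iloc[0]
            raise TableValueError(f"{col} {msg}; offending wetland_id {row!r}")
    ad = df[SINK].to_numpy()
    if not np.allclose(ad, np.round(ad)):
        raise TableValueError(f"{SINK} must be an integer species count")
    df[SINK] = np.round(ad).astype(int)
    return df


def read_trait_table(path) -> TraitTable:
    """Read and validate a trait-table CSV (comma-separated, header row)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return TraitTable(df)


# ---------------------------------------------------------------------------
# metamodel DAG
# ---------------------------------------------------------------------------


@dataclass
class MetamodelDAG:
    """Hypothesized directed acyclic metamodel of trait dependencies.

    ``arcs`` is an *ordered* list of ``(parent, child, sign)`` with sign in
    {'+', '-'}.  The arc order is significant: for a child with several
    parents it fixes the conditioning order of the arc partial correlations.
    """

    nodes: list[str]
    arcs: list[tuple[str, str, str]]
    sink: str = SINK

    def __post_init__(self) -> None:
        seen = set(self.nodes)
        if len(seen) != len(self.nodes):
            raise GraphError("duplicate node names")
        if self.sink not in seen:
            raise GraphError(f"sink {self.sink!r} not among nodes")
        norm = []
        for arc in self.arcs:
            if len(arc) == 2:
                parent, child, sign = arc[0], arc[1], "+"
            else:
                parent, child, sign = arc
            if sign not in {"+", "-"}:
                raise SchemaError(f"arc sign must be '+' or '-', got {sign!r}")
            for endpoint in (parent, child):
                if endpoint not in seen:
                    raise SchemaError(f"arc endpoint {endpoint!r} is not a declared node")
            if parent == self.sink:
                raise GraphError(f"sink {self.sink!r} has an outgoing arc to {child!r}")
            norm.append((parent, child, sign))
        self.arcs = norm
        if len({(p, c) for p, c, _ in norm}) != len(norm):
            raise GraphError("duplicate arcs")
        graph = self.graph
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise GraphError(f"metamodel contains a cycle: {cycle}")

    @property
    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for parent, child, sign in self.arcs:
            g.add_edge(parent, child, sign=sign)
        return g

    def parents(self, child: str) -> list[str]:
        """Parents of ``child`` in arc-list (conditioning) order."""
        return [p for p, c, _ in self.arcs if c == child]

    def topological_children(self) -> list[str]:
        """Nodes with at least one parent, in topological order."""
        order = list(nx.topological_sort(self.graph))
        with_parents = {c for _, c, _ in self.arcs}
        return [n for n in order if n in with_parents]

    def arc_sign(self, parent: str, child: str) -> str:
        for p, c, s in self.arcs:
            if (p, c) == (parent, child):
                return s
        raise SchemaError(f"no arc {parent!r} -> {child!r}")

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "arcs": [list(a) for a in self.arcs],
            "sink": self.sink,
        }


def _load_structured(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise SchemaError(f"{path} must hold a mapping at the top level")
    return payload


def dag_from_dict(payload: dict) -> MetamodelDAG:
    if "nodes" not in payload or "arcs" not in payload:
        raise SchemaError("DAG config needs 'nodes' and 'arcs' keys")
    return MetamodelDAG(
        nodes=list(payload["nodes"]),
        arcs=[tuple(a) for a in payload["arcs"]],
        sink=payload.get("sink", SINK),
    )


def read_dag_config(path) -> MetamodelDAG:
    """Read a YAML/JSON DAG config with keys ``nodes``, ``arcs`` (, ``sink``)."""
    return dag_from_dict(_load_structured(path))


def default_dag() -> MetamodelDAG:
    """The package's default metamodel for the Sicilian-wetlands analysis.

    Eight traits act directly on alpha diversity; distance to the coastline
    acts only through tourism pressure and water salinity, and water
    diversions only through the two water-level variables.  Anthropization
    additionally drives discharges and diversions.  This structure is a
    documented reconstruction of the published metamodel and can be
    overridden by any user-supplied config.
    """
    with resources.files("wetlandnbn.data").joinpath("default_dag.yaml").open() as fh:
        return dag_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """One named what-if conditioning.

    ``evidence`` maps trait names to fixed values.  Regional scenarios
    condition only those variables, leaving the rest distributed as fitted.
    Local (single-wetland) scenarios additionally carry ``baseline``: the
    wetland's unmodified trait values, on top of which ``evidence``
    overrides are applied.
    """

    id: str
    scope: str  # "regional" | "local"
    evidence: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        if self.scope not in {"regional", "local"}:
            raise SchemaError(f"scenario scope must be regional|local, got {self.scope!r}")
        self.evidence = {str(k): float(v) for k, v in self.evidence.items()}
        self.baseline = {str(k): float(v) for k, v in self.baseline.items()}

    def full_evidence(self) -> dict:
        """Baseline values with scenario overrides applied on top."""
        merged = dict(self.baseline)
        merged.update(self.evidence)
        return merged

    def validate_against(self, dag: MetamodelDAG) -> "ScenarioSpec":
        nodes = set(dag.nodes)
        for var in {**self.baseline, **self.evidence}:
            if var not in nodes:
                raise SchemaError(
                    f"scenario {self.id}: evidence on unknown variable {var!r}"
                )
            if var == dag.sink:
                raise ScenarioError(
                    f"scenario {self.id}: the target variable {dag.sink!r} "
                    "cannot be conditioned"
                )
        return self


def read_scenarios(path) -> list[ScenarioSpec]:
    """Read a YAML/JSON scenario file.

    Expected keys: ``scenarios`` (list of ``{id, scope, evidence}``) and,
    for local files, an optional top-level ``baseline_evidence`` applied to
    every scenario that does not define its own ``baseline``.
    """
    payload = _load_structured(path)
    entries = payload.get("scenarios", [])
    if not entries:
        logger.warning("scenario file %s defines no scenarios", path)
        return []
    shared_baseline = payload.get("baseline_evidence", {})
    default_scope = payload.get("scope", "regional")
    specs = []
    for entry in entries:
        if "id" not in entry:
            raise SchemaError("every scenario needs an 'id'")
        specs.append(
            ScenarioSpec(
                id=str(entry["id"]),
                scope=entry.get("scope", default_scope),
                evidence=entry.get("evidence", {}) or {},
                baseline=entry.get("baseline", shared_baseline) or {},
                description=entry.get("description", ""),
            )
        )
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate scenario ids")
    return specs


def _shipped(name: str) -> Path:
    return resources.files("wetlandnbn.data").joinpath(name)


def regional_scenarios() -> list[ScenarioSpec]:
    """The 21 shipped regional scenarios S_0...S_20 (baseline, worst, best, mixed)."""
    with resources.as_file(_shipped("scenarios_regional.yaml")) as p:
        return read_scenarios(p)


def local_scenarios() -> list[ScenarioSpec]:
    """The 31 shipped Pantano Bruno scenarios S_0, S_21...S_50."""
    with resources.as_file(_shipped("scenarios_local.yaml")) as p:
        return read_scenarios(p)
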