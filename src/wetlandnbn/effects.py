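"""Direct / indirect / total effect decomposition on alpha diversity.

For a trait x, the direct effect E_D is the correlation on the arc
x -> alpha_diversity (0 if there is no such arc).  The indirect effect E_I
is the sum, over every simple directed path of length >= 2 from x to the
sink, of the product of the arc correlations along the path.  The total
effect is their sum, E_T = E_D + E_I.  Effects are taken in this
operational path-sum sense, using the arc values exactly as stored on the
fitted network; no interventional (do-calculus) semantics is claimed.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .copula import FittedNBN
from .exceptions import SchemaError
from .io import MetamodelDAG

__all__ = ["enumerate_paths", "direct_effect", "indirect_effect", "effect_table"]


def enumerate_paths(dag: MetamodelDAG, source: str, sink: str) -> list[list[str]]:
    """All simple directed paths source -> sink, lexicographically ordered."""
    for node in (source, sink):
        if node not in dag.nodes:
            raise SchemaError(f"unknown node {node!r}")
    paths = nx.all_simple_paths(dag.graph, source, sink)
    return sorted(list(p) for p in paths)


def _check_trait(nbn: FittedNBN, trait: str) -> None:
    if trait not in nbn.dag.nodes:
        raise SchemaError(f"unknown trait {trait!r}")
    if trait == nbn.sink:
        raise SchemaError("the sink has no effect on itself")


def direct_effect(nbn: FittedNBN, trait: str) -> float:
    """E_D: the arc correlation trait -> sink, or 0 without a direct arc."""
    _check_trait(nbn, trait)
    return nbn.arc_correlation(trait, nbn.sink)


def indirect_effect(nbn: FittedNBN, trait: str) -> float:
    """E_I: sum over simple directed paths of length >= 2 of the product of
    arc correlations; the one-arc (direct) path is excluded."""
    _check_trait(nbn, trait)
    total = 0.0
    for path in enumerate_paths(nbn.dag, trait, nbn.sink):
        if len(path) < 3:  # direct arc: belongs to E_D
            continue
        prod = 1.0
        for parent, child in zip(path[:-1], path[1:]):
            prod *= nbn.arc_correlation(parent, child)
        total += prod
    return total


def total_effect(nbn: FittedNBN, trait: str) -> float:
    """E_T = E_D + E_I."""
    return direct_effect(nbn, trait) + indirect_effect(nbn, trait)


def effect_table(nbn: FittedNBN) -> pd.DataFrame:
    """Per-trait effect decomposition, one row per non-sink node.

    Columns: trait, direct, indirect, total; sorted by trait name; the
    total column is the exact sum of the other two.
    """
    rows = []
    for trait in sorted(n for n in nbn.dag.nodes if n != nbn.sink):
        e_d = direct_effect(nbn, trait)
        e_i = indirect_effect(nbn, trait)
        rows.append({"trait": trait, "direct": e_d, "indirect": e_i, "total": e_d + e_i})
    table = pd.DataFrame(rows, columns=["trait", "direct", "indirect", "total"])
    assert np.allclose(table["total"], table["direct"] + table["indirect"], atol=0.0)
    return table
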