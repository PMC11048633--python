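import numpy as np
import pytest

from wetlandnbn import (
    FittedNBN,
    GaussianDependence,
    MetamodelDAG,
    default_ground_truth,
    fit_nbn,
    generate,
)
from wetlandnbn.copula import EmpiricalMarginal, build_joint_correlation


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def table16(truth):
    return generate(truth, 16, seed=1)


@pytest.fixture(scope="session")
def fitted16(truth, table16):
    return fit_nbn(table16, truth.dag)


@pytest.fixture(scope="session")
def exact_nbn(truth):
    """A model whose dependence equals the default ground truth exactly."""
    return truth.exact_nbn(n_reference=2000, seed=3)


def build_toy_nbn(nodes, arc_corr, sink=None, seed=0, n_marginal=400):
    """A small all-continuous NBN with prescribed arc correlations and
    standard-normal empirical marginals; for oracle tests."""
    sink = sink or nodes[-1]
    arcs = [(p, c, "+") for (p, c) in arc_corr]
    dag = MetamodelDAG(nodes=list(nodes), arcs=arcs, sink=sink)
    R = build_joint_correlation(dag, arc_corr)
    rng = np.random.default_rng(seed)
    marginals = {
        v: EmpiricalMarginal(name=v, values=rng.standard_normal(n_marginal))
        for v in nodes
    }
    dep = GaussianDependence(order=list(nodes), R=R, arc_corr=dict(arc_corr))
    return FittedNBN(dag=dag, marginals=marginals, dependence=dep, meta={"n": n_marginal})


@pytest.fixture
def chain_nbn():
    """x -> m -> AD with arc correlations 0.6 and 0.5."""
    return build_toy_nbn(
        ["x", "m", "AD"], {("x", "m"): 0.6, ("m", "AD"): 0.5}, sink="AD"
    )
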