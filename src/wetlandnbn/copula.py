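"""Non-parametric Bayesian network core: empirical marginals joined by a
normal (Gaussian) copula over a directed acyclic metamodel.

The model has two ingredients.  Each variable keeps its *empirical* marginal
distribution (no parametric family is imposed); dependence is carried
entirely by a multivariate normal in "normal-score" space, parameterized by
a correlation matrix R assembled from per-arc (conditional) correlations.
Conditionalization — the what-if mechanism — is then ordinary conditional
multivariate-normal algebra in score space, with results mapped back to
data units through each variable's empirical quantile function.

Latent (normal-space) correlations are estimated from mixed
ordinal/continuous data: Spearman's rank correlation mapped through the
exact normal-copula relation r = 2 sin(pi * rho_s / 6) for continuous
pairs, and polyserial / polychoric maximum-likelihood estimates where an
ordinal variable is involved (rank correlations of coarsely discretized
variables are attenuated, so the sine map alone would be inconsistent for
them).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.correlation_tools import corr_clipped

from .exceptions import (
    DegenerateMarginalError,
    FitError,
    ScenarioError,
    SchemaError,
)
from .io import ORDINAL_TRAITS, MetamodelDAG, TraitTable, dag_from_dict

__all__ = [
    "EmpiricalMarginal",
    "GaussianDependence",
    "FittedNBN",
    "ConditionalLaw",
    "fit_marginal",
    "spearman_rho",
    "rank_to_product_moment",
    "product_moment_to_rank",
    "latent_correlation_matrix",
    "fit_nbn",
    "build_joint_correlation",
    "conditionalize",
    "predict_target",
    "sample_joint",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# empirical marginals
# ---------------------------------------------------------------------------


@dataclass
class EmpiricalMarginal:
    """Empirical marginal distribution of one variable.

    The CDF uses average-rank plotting positions rank/(n+1), which keeps F
    strictly inside (0, 1).  For continuous variables the quantile function
    interpolates linearly between order statistics; for discrete (ordinal)
    variables it is the step inverse of the ECDF, so sampled values always
    belong to the observed support.
    """

    name: str
    values: np.ndarray  # sorted observations
    discrete: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 3:
            raise DegenerateMarginalError(
                f"{self.name}: need at least 3 observations"
            )
        if not np.all(np.isfinite(v)):
            raise DegenerateMarginalError(f"{self.name}: non-finite observations")
        self.values = np.sort(v)
        if self.values[0] == self.values[-1]:
            raise DegenerateMarginalError(
                f"{self.name}: all observations identical "
                f"({self.values[0]}); variable carries no information"
            )
        n = len(self.values)
        self.n = n
        self.distinct, counts = np.unique(self.values, return_counts=True)
        # average-rank plotting position of each distinct value
        cum = np.cumsum(counts)
        avg_rank = cum - (counts - 1) / 2.0
        self.positions = avg_rank / (n + 1)
        self._cum_frac = cum / n  # ECDF step tops, for the discrete inverse

    @property
    def support(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def cdf(self, x) -> np.ndarray:
        """F(x) in the open interval (0, 1); clamped outside the support."""
        x = np.asarray(x, dtype=float)
        if self.discrete:
            below = np.searchsorted(self.values, x, side="left")
            equal = np.searchsorted(self.values, x, side="right") - below
            f = (below + (equal + 1) / 2.0) / (self.n + 1)
        else:
            f = np.interp(x, self.distinct, self.positions)
        lo, hi = 1.0 / (self.n + 1), self.n / (self.n + 1)
        return np.clip(f, lo, hi)

    def quantile(self, u) -> np.ndarray:
        """Q(u): inverse of the empirical distribution, u in (0, 1)."""
        u = np.asarray(u, dtype=float)
        if self.discrete:
            idx = np.searchsorted(self._cum_frac, u, side="left")
            idx = np.clip(idx, 0, len(self.distinct) - 1)
            return self.distinct[idx]
        return np.interp(u, self.positions, self.distinct)

    def normal_score(self, x, warn_outside: bool = True) -> float:
        """Map a value to its normal score z = Phi^-1(F(x)).

        Values outside the observed support are clamped to the extreme
        plotting positions 1/(n+1) and n/(n+1): evidence beyond the observed
        maximum cannot push the conditional distribution further (quantile
        saturation).
        """
        lo, hi = self.support
        if warn_outside and (x < lo or x > hi):
            warnings.warn(
                f"{self.name}: evidence value {x} outside observed support "
                f"[{lo}, {hi}]; clamped to the nearest extreme quantile",
                stacklevel=2,
            )
        return float(stats.norm.ppf(self.cdf(x)))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "values": self.values.tolist(),
            "discrete": bool(self.discrete),
        }


def fit_marginal(samples, name: str = "x", discrete: bool = False) -> EmpiricalMarginal:
    """Build an empirical marginal from raw observations."""
    return EmpiricalMarginal(name=name, values=np.asarray(samples, float), discrete=discrete)


# ---------------------------------------------------------------------------
# rank correlation and the normal-copula conversion
# ---------------------------------------------------------------------------


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation.

    Without ties this equals 1 - 6 * sum(d_i^2) / (n^3 - n) with d_i the
    rank difference of observation i; with ties it is the product-moment
    correlation of average ranks (the formula's standard generalization).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise SchemaError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise SchemaError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateMarginalError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def rank_to_product_moment(rho_s: float) -> float:
    """Spearman -> Pearson conversion r = 2 sin(pi * rho_s / 6).

    Exact for the bivariate normal (hence for the normal copula).
    """
    if abs(rho_s) > 1:
        raise SchemaError(f"|rho_s| must be <= 1, got {rho_s}")
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def product_moment_to_rank(r: float) -> float:
    """Inverse conversion rho_s = (6/pi) arcsin(r/2)."""
    if abs(r) > 1:
        raise SchemaError(f"|r| must be <= 1, got {r}")
    return float(6.0 / np.pi * np.arcsin(r / 2.0))


# -- polyserial / polychoric latent correlations ----------------------------


def _normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x)
    return stats.norm.ppf(ranks / (len(x) + 1))


def _thresholds(ordinal: np.ndarray):
    cats, counts = np.unique(ordinal, return_counts=True)
    cum = np.cumsum(counts) / len(ordinal)
    tau = stats.norm.ppf(cum[:-1])
    return cats, tau


def polyserial_corr(ordinal, cont) -> float:
    """Two-step polyserial latent correlation (ordinal vs continuous).

    The continuous variable is mapped to van der Waerden normal scores; the
    latent correlation solves Cov(z, y) = rho * sum_k (s_{k+1}-s_k) phi(tau_k)
    with thresholds tau_k from the ordinal's cumulative proportions.
    """
    ordinal = np.asarray(ordinal, float)
    cont = np.asarray(cont, float)
    cats, tau = _thresholds(ordinal)
    if len(cats) < 2:
        raise DegenerateMarginalError("polyserial: ordinal variable is constant")
    z = _normal_scores(cont)
    cov = float(np.cov(z, ordinal, ddof=1)[0, 1])
    denom = float(np.sum(np.diff(cats) * stats.norm.pdf(tau))) * float(np.std(z, ddof=1))
    return float(np.clip(cov / denom, -0.999, 0.999))


def _bvn_cell_probs(tau_x, tau_y, r) -> np.ndarray:
    """Cell probabilities of a discretized bivariate normal with corr r."""
    gx = np.concatenate([[-np.inf], tau_x, [np.inf]])
    gy = np.concatenate([[-np.inf], tau_y, [np.inf]])
    nx_, ny_ = len(gx), len(gy)
    C = np.zeros((nx_, ny_))
    C[-1, -1] = 1.0
    C[-1, 1:-1] = stats.norm.cdf(gy[1:-1])
    C[1:-1, -1] = stats.norm.cdf(gx[1:-1])
    if len(tau_x) and len(tau_y):
        pts = np.array([[a, b] for a in gx[1:-1] for b in gy[1:-1]])
        vals = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]], allow_singular=True
        ).cdf(pts)
        C[1:-1, 1:-1] = np.asarray(vals).reshape(len(tau_x), len(tau_y))
    P = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
    return np.clip(P, 1e-12, 1.0)


def polychoric_corr(x, y) -> float:
    """Two-step polychoric latent correlation (ordinal vs ordinal), by
    one-dimensional maximum likelihood with thresholds fixed at the
    marginal cumulative proportions."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cx, tau_x = _thresholds(x)
    cy, tau_y = _thresholds(y)
    if len(cx) < 2 or len(cy) < 2:
        raise DegenerateMarginalError("polychoric: a variable is constant")
    table = np.zeros((len(cx), len(cy)))
    for i, a in enumerate(cx):
        mask = x == a
        for j, b in enumerate(cy):
            table[i, j] = np.sum(mask & (y == b))

    def nll(r):
        return -float(np.sum(table * np.log(_bvn_cell_probs(tau_x, tau_y, r))))

    res = optimize.minimize_scalar(
        nll, bounds=(-0.995, 0.995), method="bounded", options={"xatol": 5e-4}
    )
    return float(res.x)


def infer_discrete(df) -> dict:
    """Heuristic per-column discreteness: schema ordinals, or any column
    taking at most four distinct values inside {0, 1, 2, 3}."""
    out = {}
    for col in df.columns:
        v = df[col].to_numpy()
        if col in ORDINAL_TRAITS:
            out[col] = True
        else:
            distinct = np.unique(v)
            out[col] = bool(
                len(distinct) <= 4 and np.all(np.isin(distinct, [0, 1, 2, 3]))
            )
    return out


def latent_correlation_matrix(df, discrete: dict | None = None, method: str = "auto"):
    """Pairwise normal-space correlation matrix of a mixed data frame.

    method="auto": continuous pairs via Spearman + 2 sin(pi rho/6); pairs
    involving an ordinal via polyserial/polychoric estimates.
    method="spearman": the sine conversion for every pair.
    The result is repaired to the nearest positive-definite correlation
    matrix when sampling noise pushes it outside the cone.
    """
    cols = list(df.columns)
    if discrete is None:
        discrete = infer_discrete(df)
    d = len(cols)
    S = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            xi = df[cols[i]].to_numpy(float)
            xj = df[cols[j]].to_numpy(float)
            di, dj = discrete.get(cols[i], False), discrete.get(cols[j], False)
            if method == "spearman" or not (di or dj):
                r = rank_to_product_moment(spearman_rho(xi, xj))
            elif di and dj:
                r = polychoric_corr(xi, xj)
            elif di:
                r = polyserial_corr(xi, xj)
            else:
                r = polyserial_corr(xj, xi)
            S[i, j] = S[j, i] = r
    eigmin = float(np.linalg.eigvalsh(S).min())
    if eigmin < -1e-10:  # indefinite from sampling noise: repair
        S = np.asarray(corr_clipped(S, threshold=1e-6))
        S = (S + S.T) / 2.0
    return S


# ---------------------------------------------------------------------------
# joint dependence structure
# ---------------------------------------------------------------------------


@dataclass
class GaussianDependence:
    """Normal-score-space dependence: node order, joint correlation matrix R,
    and the per-arc (conditional) correlations it was assembled from."""

    order: list[str]
    R: np.ndarray
    arc_corr: dict  # (parent, child) -> rho

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, float)
        d = len(self.order)
        if self.R.shape != (d, d):
            raise SchemaError("R shape does not match node order")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise SchemaError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-10):
            raise SchemaError("R must have a unit diagonal")
        self._index = {name: k for k, name in enumerate(self.order)}

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None


def _gram_schmidt_coeffs(cond_corrs: list[float]) -> tuple[np.ndarray, float]:
    """Vine recursion: conditional correlations -> orthonormal-basis loadings.

    c_j = r_j * sqrt(1 - sum_{m<j} c_m^2); the residual loading c_0 makes
    the variance 1.  Valid (and positive semi-definite) for any r_j in [-1, 1].
    """
    loadings = []
    rem = 1.0
    for r in cond_corrs:
        c = r * np.sqrt(max(rem, 0.0))
        loadings.append(c)
        rem -= c * c
    return np.array(loadings), float(np.sqrt(max(rem, 0.0)))


def build_joint_correlation(dag: MetamodelDAG, arc_corr: dict) -> np.ndarray:
    """Assemble the joint normal-score correlation matrix from per-arc
    conditional correlations (parents conditioned in arc-list order).

    Root variables are independent; every non-adjacent correlation is the
    one implied by the DAG factorization.  The construction is a truncated
    vine, so R is positive semi-definite for any arc values in [-1, 1].
    """
    order = list(dag.nodes)
    idx = {n: k for k, n in enumerate(order)}
    d = len(order)
    R = np.eye(d)
    built: list[str] = [n for n in order if not dag.parents(n)]
    for child in dag.topological_children():
        parents = dag.parents(child)
        missing = [p for p in parents if p not in built]
        if missing:
            raise FitError(f"parents {missing} of {child!r} not built yet")
        r_cond = []
        for p in parents:
            key = (p, child)
            if key not in arc_corr:
                raise SchemaError(f"no correlation for arc {p!r} -> {child!r}")
            r_cond.append(float(np.clip(arc_corr[key], -1.0, 1.0)))
        p_idx = [idx[p] for p in parents]
        sigma_pp = R[np.ix_(p_idx, p_idx)]
        try:
            L = np.linalg.cholesky(sigma_pp + 1e-12 * np.eye(len(p_idx)))
        except np.linalg.LinAlgError as exc:
            raise FitError(
                f"parent covariance of {child!r} is singular; inspect the "
                "arc order or the data"
            ) from exc
        c_vec, _ = _gram_schmidt_coeffs(r_cond)
        # Cov(child, y) = c_vec' L^-1 Cov(parents, y) for every built y
        b_idx = [idx[b] for b in built]
        sigma_py = R[np.ix_(p_idx, b_idx)]
        cov_cy = c_vec @ np.linalg.solve(L, sigma_py)
        for k, y in enumerate(b_idx):
            R[idx[child], y] = R[y, idx[child]] = cov_cy[k]
        built.append(child)
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < -1e-8:
        raise FitError(f"assembled R is not positive semi-definite (min eig {eigmin})")
    if eigmin < 1e-10:
        warnings.warn(
            "assembled R is singular at the boundary (an arc correlation of "
            "+-1); conditional laws may be degenerate",
            stacklevel=2,
        )
    return R


def _partial_corr_from_matrix(S: np.ndarray, i: int, j: int, given: list[int]) -> float:
    if not given:
        return float(S[i, j])
    sub = S[np.ix_([i, j] + given, [i, j] + given)]
    try:
        P = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise FitError(
            "singular correlation submatrix while computing an arc partial "
            "correlation; inspect the arc order or the data"
        ) from exc
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


# ---------------------------------------------------------------------------
# the fitted model
# ---------------------------------------------------------------------------


@dataclass
class FittedNBN:
    """A calibrated non-parametric Bayesian network."""

    dag: MetamodelDAG
    marginals: dict  # name -> EmpiricalMarginal
    dependence: GaussianDependence
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.marginals) != set(self.dependence.order):
            raise SchemaError("marginals and dependence cover different node sets")

    @property
    def sink(self) -> str:
        return self.dag.sink

    def arc_correlation(self, parent: str, child: str) -> float:
        return self.dependence.arc_corr.get((parent, child), 0.0)

    def to_dict(self) -> dict:
        return {
            "dag": self.dag.to_dict(),
            "marginals": {k: m.to_dict() for k, m in self.marginals.items()},
            "order": list(self.dependence.order),
            "R": self.dependence.R.tolist(),
            "arc_corr": [
                {"parent": p, "child": c, "rho": float(r)}
                for (p, c), r in self.dependence.arc_corr.items()
            ],
            "meta": self.meta,
        }


def fit_nbn(
    traits,
    dag: MetamodelDAG,
    method: str = "auto",
    discrete: dict | None = None,
) -> FittedNBN:
    """Calibrate the NBN from a trait table and a metamodel DAG.

    Per node an empirical marginal; per arc (parent -> child) the
    normal-space correlation of parent and child conditioned on the child's
    parents listed earlier in the arc order; the joint R is assembled so its
    implied conditional correlations match the arc values, with all
    non-adjacent dependence implied by the DAG factorization.
    """
    df = traits.data if isinstance(traits, TraitTable) else traits
    missing = [n for n in dag.nodes if n not in df.columns]
    if missing:
        raise SchemaError(f"DAG node(s) missing from the table: {missing}")
    sub = df.loc[:, list(dag.nodes)]
    if discrete is None:
        discrete = infer_discrete(sub)

    marginals = {
        n: fit_marginal(sub[n].to_numpy(float), name=n, discrete=discrete.get(n, False))
        for n in dag.nodes
    }
    S = latent_correlation_matrix(sub, discrete=discrete, method=method)
    idx = {n: k for k, n in enumerate(dag.nodes)}
    arc_corr = {}
    for child in dag.topological_children():
        earlier: list[int] = []
        for p in dag.parents(child):
            arc_corr[(p, child)] = _partial_corr_from_matrix(
                S, idx[p], idx[child], list(earlier)
            )
            earlier.append(idx[p])
    R = build_joint_correlation(dag, arc_corr)
    meta = {
        "n": int(len(sub)),
        "method": method,
        "discrete": {k: bool(v) for k, v in discrete.items()},
    }
    return FittedNBN(dag=dag, marginals=marginals, dependence=GaussianDependence(
        order=list(dag.nodes), R=R, arc_corr=arc_corr), meta=meta)


# ---------------------------------------------------------------------------
# conditionalization and sampling
# ---------------------------------------------------------------------------


@dataclass
class ConditionalLaw:
    """Conditional multivariate normal of the free variables given evidence,
    with handles to map samples back to data units."""

    nbn: FittedNBN
    free: list[str]
    evidence_scores: dict  # var -> z
    mean: np.ndarray
    cov: np.ndarray

    def index(self, var: str) -> int:
        try:
            return self.free.index(var)
        except ValueError:
            raise SchemaError(f"{var!r} is not a free variable") from None

    def marginal_normal(self, var: str) -> tuple[float, float]:
        """(mean, sd) of one free variable in normal-score space."""
        k = self.index(var)
        return float(self.mean[k]), float(np.sqrt(max(self.cov[k, k], 0.0)))

    def sample(self, n: int, seed=None) -> dict:
        """Draw n joint samples of the free variables, mapped through the
        empirical quantile functions; returns a dict of arrays."""
        rng = np.random.default_rng(seed)
        z = rng.multivariate_normal(self.mean, self.cov, size=n, method="eigh")
        u = stats.norm.cdf(z)
        return {
            v: self.nbn.marginals[v].quantile(u[:, k])
            for k, v in enumerate(self.free)
        }


def conditionalize(nbn: FittedNBN, evidence: dict) -> ConditionalLaw:
    """Condition the NBN on fixed values of some variables.

    Evidence is mapped to normal scores through each variable's empirical
    marginal (ordinal values at the midpoint of their ECDF step; values
    outside the observed support clamped to the extreme plotting positions),
    then standard conditional-MVN algebra is applied to R.
    """
    order = nbn.dependence.order
    for var in evidence:
        if var not in order:
            raise SchemaError(f"evidence on unknown variable {var!r}")
        if var == nbn.sink:
            raise ScenarioError(f"the target variable {nbn.sink!r} cannot be evidence")
    ev_vars = [v for v in order if v in evidence]
    free = [v for v in order if v not in evidence]
    z_e = {v: nbn.marginals[v].normal_score(evidence[v]) for v in ev_vars}

    R = nbn.dependence.R
    f_idx = [order.index(v) for v in free]
    e_idx = [order.index(v) for v in ev_vars]
    if not ev_vars:
        return ConditionalLaw(nbn, free, {}, np.zeros(len(free)), R.copy())
    R_ff = R[np.ix_(f_idx, f_idx)]
    R_fe = R[np.ix_(f_idx, e_idx)]
    R_ee = R[np.ix_(e_idx, e_idx)]
    z_vec = np.array([z_e[v] for v in ev_vars])
    try:
        solve_e = np.linalg.solve(R_ee, np.column_stack([z_vec]))
        gain = np.linalg.solve(R_ee, R_fe.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular conditioning block in R") from exc
    mean = R_fe @ solve_e[:, 0]
    cov = R_ff - R_fe @ gain
    cov = (cov + cov.T) / 2.0
    return ConditionalLaw(nbn, free, z_e, mean, cov)


def predict_target(
    nbn: FittedNBN,
    evidence: dict,
    n_samples: int = 100_000,
    seed=None,
) -> tuple[float, float]:
    """Monte-Carlo mean and SD of the sink (species units) given evidence.

    Draws from the sink's conditional normal and maps each draw through the
    sink's empirical quantile function; a fixed seed makes the result
    reproducible bit for bit.
    """
    law = conditionalize(nbn, evidence)
    mu, sd = law.marginal_normal(nbn.sink)
    rng = np.random.default_rng(seed)
    z = mu + sd * rng.standard_normal(int(n_samples))
    values = nbn.marginals[nbn.sink].quantile(stats.norm.cdf(z))
    return float(np.mean(values)), float(np.std(values, ddof=0))


def sample_joint(nbn: FittedNBN, n: int, seed=None):
    """Draw n rows from the fitted joint law (a trait-table-shaped frame).

    Latent draws come from the joint normal with correlation R; each column
    is mapped through its empirical quantile function, so ordinal columns
    take values from the observed support only.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    order = nbn.dependence.order
    z = rng.multivariate_normal(
        np.zeros(len(order)), nbn.dependence.R, size=int(n), method="eigh"
    )
    u = stats.norm.cdf(z)
    data = {
        v: nbn.marginals[v].quantile(u[:, k]) for k, v in enumerate(order)
    }
    return pd.DataFrame(data, columns=list(order))


# ---------------------------------------------------------------------------
# model serialization (JSON interchange)
# ---------------------------------------------------------------------------


def save_model(nbn: FittedNBN, path) -> None:
    Path(path).write_text(json.dumps(nbn.to_dict(), indent=1), encoding="utf-8")


def load_model(path) -> FittedNBN:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    dag = dag_from_dict(payload["dag"])
    marginals = {
        k: EmpiricalMarginal(
            name=m["name"], values=np.array(m["values"]), discrete=m["discrete"]
        )
        for k, m in payload["marginals"].items()
    }
    arc_corr = {
        (a["parent"], a["child"]): float(a["rho"]) for a in payload["arc_corr"]
    }
    dep = GaussianDependence(
        order=list(payload["order"]), R=np.array(payload["R"]), arc_corr=arc_corr
    )
    return FittedNBN(dag=dag, marginals=marginals, dependence=dep, meta=payload.get("meta", {}))
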