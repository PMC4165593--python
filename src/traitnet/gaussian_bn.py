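"""Gaussian Bayesian networks over species-level trait/demography tables.

A directed acyclic graph (DAG) over the study variables, together with one
Gaussian linear model per node,

    X_v | pa(v)  ~  Normal( m_v + sum_p beta_vp X_p ,  sigma2_v ),

defines a joint likelihood that factorizes over parent--child clusters. The
network structure is learned by score-based search (greedy hill climbing
with random perturbations and restarts) under tiered edge constraints that
encode the ecological hierarchy: functional traits may drive demographic
rates, demographic rates may drive the population change rate, and no arrow
may point back down the hierarchy.

Two decomposable, score-equivalent scores are available: BIC (default) and
a Bayesian Gaussian score with a weakly informative normal-Wishart prior
whose strength is set by an imaginary sample size (``bayes_cg``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import multigammaln

TIERS = ("trait", "demographic", "performance")


# ---------------------------------------------------------------------------
# Data container and transform
# ---------------------------------------------------------------------------

@dataclass
class AnalysisMatrix:
    """Species x variable numeric table after transformation.

    ``data`` holds one row per species; ``tiers`` maps every variable to
    ``trait``, ``demographic`` or ``performance``; ``log_vars`` records which
    columns are on a natural-log scale.
    """

    data: pd.DataFrame
    tiers: dict[str, str]
    log_vars: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("analysis matrix contains missing values")
        unknown = set(self.tiers.values()) - set(TIERS)
        if unknown:
            raise ValueError(f"unknown tiers: {sorted(unknown)}")
        missing = set(self.data.columns) - set(self.tiers)
        if missing:
            raise ValueError(f"variables without a tier: {sorted(missing)}")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def transform(
    raw: pd.DataFrame,
    tiers: Mapping[str, str],
    log_vars: Sequence[str] = (),
    offsets: Mapping[str, float] | str = "half_min_positive",
) -> AnalysisMatrix:
    """Log-transform selected variables so their distributions approach
    normality, and attach the tier map.

    Parameters
    ----------
    offsets
        Either an explicit ``{variable: offset}`` map (missing variables get
        offset 0) or the policy ``"half_min_positive"``: when a column to be
        logged contains an exact zero (e.g. a species with no observed
        deaths), half its smallest positive value is added before taking the
        log.
    """
    cols = [c for c in raw.columns if c in tiers]
    data = raw[cols].astype(float).copy()
    if data.isna().any().any():
        bad = data.columns[data.isna().any()].tolist()
        raise ValueError(f"missing values in variables {bad}")
    for var in log_vars:
        if var not in data.columns:
            raise ValueError(f"log variable {var!r} not in table")
        col = data[var]
        if offsets == "half_min_positive":
            off = 0.0
            if (col <= 0).any():
                positive = col[col > 0]
                if positive.empty:
                    raise ValueError(f"variable {var!r} has no positive values")
                off = 0.5 * float(positive.min())
        elif isinstance(offsets, Mapping):
            off = float(offsets.get(var, 0.0))
        else:
            raise ValueError(f"unknown offset policy {offsets!r}")
        shifted = col + off
        if (shifted <= 0).any():
            species = shifted.index[shifted <= 0].tolist()
            raise ValueError(
                f"cannot log-transform {var!r}: nonpositive value for "
                f"species {species} (offset {off})"
            )
        data[var] = np.log(shifted)
    return AnalysisMatrix(
        data=data, tiers=dict(tiers), log_vars=tuple(log_vars)
    )


# ---------------------------------------------------------------------------
# DAG and tier constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph as a node tuple and a frozenset of edges."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_edges(
        cls, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()
    ) -> "Dag":
        nodes = tuple(nodes)
        node_set = set(nodes)
        edges = frozenset((str(u), str(v)) for u, v in edges)
        for u, v in edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
            if u == v:
                raise ValueError(f"self-loop on {u}")
        dag = cls(nodes=nodes, edges=edges)
        if not dag.is_acyclic():
            raise ValueError("edge set contains a directed cycle")
        return dag

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, w in self.edges if w == v))

    def children(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(w for u, w in self.edges if u == v))

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges

    def adjacent(self, u: str, v: str) -> bool:
        return (u, v) in self.edges or (v, u) in self.edges

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def topological_order(self) -> list[str]:
        # lexicographic tie-break makes downstream enumeration deterministic
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.edges)

    # --- edge surgery (returns new Dag; legality checked by caller) ---

    def with_edge(self, u: str, v: str) -> "Dag":
        return Dag(self.nodes, self.edges | {(u, v)})

    def without_edge(self, u: str, v: str) -> "Dag":
        return Dag(self.nodes, self.edges - {(u, v)})

    def with_reversed(self, u: str, v: str) -> "Dag":
        return Dag(self.nodes, (self.edges - {(u, v)}) | {(v, u)})

    def has_path(self, src: str, dst: str) -> bool:
        """Directed reachability src -> dst (used for cycle checks)."""
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for a, b in self.edges:
            children[a].append(b)
        stack, seen = [src], {src}
        while stack:
            node = stack.pop()
            if node == dst:
                return True
            for nxt in children[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    # --- serialization ---

    def to_json(self) -> str:
        return json.dumps(
            {"nodes": list(self.nodes), "edges": sorted(map(list, self.edges))},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Dag":
        obj = json.loads(text)
        return cls.from_edges(obj["nodes"], [tuple(e) for e in obj["edges"]])

    def to_dot(self, name: str = "dag") -> str:
        lines = [f"digraph {name} {{"]
        for node in self.nodes:
            lines.append(f'  "{node}";')
        for u, v in sorted(self.edges):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class TierConstraints:
    """Banned-edge set derived from the trait -> demographic -> performance
    hierarchy: nothing leaves the performance tier, demographic rates never
    point at traits, traits never point directly at performance."""

    tiers: Mapping[str, str]

    def is_banned(self, u: str, v: str) -> bool:
        tu, tv = self.tiers[u], self.tiers[v]
        if tu == "performance":
            return True
        if tu == "demographic" and tv == "trait":
            return True
        if tu == "trait" and tv == "performance":
            return True
        return False

    def banned_edges(self, nodes: Iterable[str]) -> set[tuple[str, str]]:
        nodes = list(nodes)
        return {
            (u, v)
            for u in nodes
            for v in nodes
            if u != v and self.is_banned(u, v)
        }

    def allows(self, dag: Dag) -> bool:
        return not any(self.is_banned(u, v) for u, v in dag.edges)


# ---------------------------------------------------------------------------
# Node models and scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianNodeModel:
    """Gaussian linear model of one node given its parents."""

    node: str
    parents: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    sigma2: float          # maximum-likelihood residual variance (divisor n)
    sigma2_unbiased: float  # divisor n - k - 1, for reporting
    r2: float
    n: int


@dataclass(frozen=True)
class SearchConfig:
    """Settings for score-based structure search."""

    score_type: str = "bic"
    prior_ess: float = 4.0
    restarts: int = 20
    perturb_moves: int = 10
    seed: int = 0
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.score_type not in ("bic", "bayes_cg"):
            raise ValueError(f"unknown score_type {self.score_type!r}")
        if self.restarts < 1 or self.perturb_moves < 0:
            raise ValueError("restarts must be >= 1 and perturb_moves >= 0")


def fit_node(
    data: AnalysisMatrix, node: str, parents: Sequence[str]
) -> GaussianNodeModel:
    """Least-squares fit of one node on its parents.

    Reports the maximum-likelihood residual variance (divisor n, used in
    scoring) alongside the unbiased estimate, and the usual coefficient of
    determination r2 (zero for a parentless node).
    """
    parents = tuple(parents)
    if node in parents:
        raise ValueError(f"node {node!r} cannot be its own parent")
    y = data.data[node].to_numpy(dtype=float)
    n = len(y)
    k = len(parents)
    if n <= k + 1:
        raise ValueError(f"need n > |parents| + 1, got n={n}, k={k}")
    if k == 0:
        resid = y - y.mean()
        sigma2 = float(resid @ resid / n)
        return GaussianNodeModel(
            node=node,
            parents=(),
            intercept=float(y.mean()),
            coefficients={},
            sigma2=sigma2,
            sigma2_unbiased=float(resid @ resid / (n - 1)),
            r2=0.0,
            n=n,
        )
    X = np.column_stack([np.ones(n), data.data[list(parents)].to_numpy(float)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k + 1:
        raise ValueError(f"collinear parents for node {node!r}")
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    return GaussianNodeModel(
        node=node,
        parents=parents,
        intercept=float(coef[0]),
        coefficients={p: float(b) for p, b in zip(parents, coef[1:])},
        sigma2=rss / n,
        sigma2_unbiased=rss / (n - k - 1),
        r2=r2,
        n=n,
    )


class _ScoreCache:
    """Decomposable family scores from sufficient statistics.

    All scores are computed from the sample size, means and the (MLE)
    covariance matrix, so a family evaluation is a small linear solve, and
    results are cached by (node, parent set) across the whole search.
    """

    def __init__(self, data: AnalysisMatrix, config: SearchConfig):
        self.config = config
        self.variables = data.variables
        self.index = {v: i for i, v in enumerate(self.variables)}
        X = data.values()
        self.n = X.shape[0]
        self.d = X.shape[1]
        self.mean = X.mean(axis=0)
        centered = X - self.mean
        self.cov = centered.T @ centered / self.n  # MLE, divisor n
        self._cache: dict[tuple[str, frozenset], float] = {}
        if config.score_type == "bayes_cg":
            # normal-Wishart prior centred on the sample mean with imaginary
            # sample size prior_ess; scatter prior t*I keeps the prior
            # covariance proportional to the identity
            self.am = float(config.prior_ess)
            self.aw = self.am + self.d + 1.0
            t = self.am * (self.aw - self.d - 1.0) / (self.am + 1.0)
            scatter = self.n * self.cov
            self._T_diag = t
            self._R = t * np.eye(self.d) + scatter
            self._subset_cache: dict[frozenset, float] = {}

    # -- residual variance of node given parents, from the covariance --

    def _mle_resid_var(self, node: str, parents: frozenset) -> float:
        i = self.index[node]
        if not parents:
            return float(self.cov[i, i])
        idx = [self.index[p] for p in sorted(parents)]
        Spp = self.cov[np.ix_(idx, idx)]
        Spv = self.cov[idx, i]
        try:
            beta = np.linalg.solve(Spp, Spv)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"collinear parents for node {node!r}") from exc
        return float(self.cov[i, i] - Spv @ beta)

    def family_score(self, node: str, parents: Iterable[str]) -> float:
        key = (node, frozenset(parents))
        if key not in self._cache:
            if self.config.score_type == "bic":
                score = self._bic(node, key[1])
            else:
                score = self._bge(node, key[1])
            self._cache[key] = score
        return self._cache[key]

    def _bic(self, node: str, parents: frozenset) -> float:
        sigma2 = self._mle_resid_var(node, parents)
        if sigma2 <= 0:
            raise ValueError(
                f"degenerate family for {node!r}: zero residual variance"
            )
        n, k = self.n, len(parents)
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        return loglik - 0.5 * (k + 2) * math.log(n)

    # -- Bayesian Gaussian score (BGe form, score equivalent) --

    def _log_subset_marginal(self, subset: frozenset) -> float:
        """Log marginal likelihood of the variables in ``subset`` under the
        conjugate normal-Wishart prior (effective Wishart dof aw - d + l for
        a subset of size l, which makes the score decomposable and
        equivalent across Markov-equivalent DAGs)."""
        if subset in self._subset_cache:
            return self._subset_cache[subset]
        l = len(subset)
        if l == 0:
            return 0.0
        idx = [self.index[v] for v in sorted(subset)]
        a_l = self.aw - self.d + l
        n = self.n
        T_sub_logdet = l * math.log(self._T_diag)
        sign, R_logdet = np.linalg.slogdet(self._R[np.ix_(idx, idx)])
        if sign <= 0:
            raise ValueError("posterior scatter matrix not positive definite")
        val = (
            -0.5 * n * l * math.log(math.pi)
            + 0.5 * l * math.log(self.am / (self.am + n))
            + multigammaln(0.5 * (a_l + n), l)
            - multigammaln(0.5 * a_l, l)
            + 0.5 * a_l * T_sub_logdet
            - 0.5 * (a_l + n) * R_logdet
        )
        self._subset_cache[subset] = val
        return val

    def _bge(self, node: str, parents: frozenset) -> float:
        family = parents | {node}
        return self._log_subset_marginal(family) - self._log_subset_marginal(
            parents
        )


def family_score(
    data: AnalysisMatrix,
    node: str,
    parents: Sequence[str],
    config: SearchConfig | None = None,
) -> float:
    """Log score of one parent--child cluster (BIC by default)."""
    cache = _ScoreCache(data, config or SearchConfig())
    return cache.family_score(node, parents)


def network_score(
    data: AnalysisMatrix, dag: Dag, config: SearchConfig | None = None
) -> float:
    """Decomposable log score of a DAG: the sum of its family scores."""
    cache = _ScoreCache(data, config or SearchConfig())
    return sum(cache.family_score(v, dag.parents(v)) for v in dag.nodes)


@dataclass
class NetworkFit:
    """A DAG with fitted per-node Gaussian models and its total score."""

    dag: Dag
    node_models: dict[str, GaussianNodeModel]
    score: float
    score_type: str
    score_trace: list[float] = field(default_factory=list)

    def r2_table(self) -> pd.DataFrame:
        rows = [
            {
                "node": m.node,
                "parents": ",".join(m.parents),
                "intercept": m.intercept,
                "r2": m.r2,
                "sigma2": m.sigma2_unbiased,
            }
            for m in self.node_models.values()
        ]
        return pd.DataFrame(rows).set_index("node")

    def coefficient_table(self) -> pd.DataFrame:
        rows = [
            {"parent": p, "child": m.node, "beta": b}
            for m in self.node_models.values()
            for p, b in m.coefficients.items()
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "beta"])


def fit_network(
    data: AnalysisMatrix, dag: Dag, config: SearchConfig | None = None
) -> NetworkFit:
    """Fit every node on its parents and attach the total network score."""
    config = config or SearchConfig()
    models = {v: fit_node(data, v, dag.parents(v)) for v in dag.nodes}
    return NetworkFit(
        dag=dag,
        node_models=models,
        score=network_score(data, dag, config),
        score_type=config.score_type,
    )


# ---------------------------------------------------------------------------
# Structure search
# ---------------------------------------------------------------------------

def _legal_moves(
    dag: Dag, banned: set[tuple[str, str]]
) -> list[tuple[str, str, str]]:
    """All single-edge moves (kind, u, v) preserving acyclicity and bans."""
    moves = []
    for u in dag.nodes:
        for v in dag.nodes:
            if u == v:
                continue
            if dag.has_edge(u, v):
                moves.append(("delete", u, v))
                if (v, u) not in banned and not dag.without_edge(u, v).has_path(
                    u, v
                ):
                    moves.append(("reverse", u, v))
            elif (u, v) not in banned and not dag.has_edge(v, u):
                if not dag.has_path(v, u):
                    moves.append(("add", u, v))
    return moves


def _apply_move(dag: Dag, move: tuple[str, str, str]) -> Dag:
    kind, u, v = move
    if kind == "add":
        return dag.with_edge(u, v)
    if kind == "delete":
        return dag.without_edge(u, v)
    return dag.with_reversed(u, v)


def _move_delta(
    cache: _ScoreCache, dag: Dag, move: tuple[str, str, str]
) -> float:
    """Score change of a move, rescoring only the affected families."""
    kind, u, v = move
    old_pa_v = dag.parents(v)
    if kind == "add":
        new_pa_v = tuple(sorted(set(old_pa_v) | {u}))
    elif kind == "delete":
        new_pa_v = tuple(p for p in old_pa_v if p != u)
    else:
        new_pa_v = tuple(p for p in old_pa_v if p != u)
    delta = cache.family_score(v, new_pa_v) - cache.family_score(v, old_pa_v)
    if kind == "reverse":
        old_pa_u = dag.parents(u)
        new_pa_u = tuple(sorted(set(old_pa_u) | {v}))
        delta += cache.family_score(u, new_pa_u) - cache.family_score(
            u, old_pa_u
        )
    return delta


def _hill_climb(
    cache: _ScoreCache,
    dag: Dag,
    banned: set[tuple[str, str]],
    max_iter: int,
) -> tuple[Dag, float, list[float]]:
    score = sum(cache.family_score(v, dag.parents(v)) for v in dag.nodes)
    trace = [score]
    for _ in range(max_iter):
        moves = _legal_moves(dag, banned)
        best_move, best_delta = None, 1e-10  # strict improvement only
        for move in moves:
            delta = _move_delta(cache, dag, move)
            if delta > best_delta:
                best_move, best_delta = move, delta
        if best_move is None:
            break
        dag = _apply_move(dag, best_move)
        score += best_delta
        trace.append(score)
    return dag, score, trace


def learn_structure(
    data: AnalysisMatrix,
    constraints: TierConstraints | None = None,
    config: SearchConfig | None = None,
) -> NetworkFit:
    """Learn a DAG by constrained greedy hill climbing with perturbation
    restarts.

    Starting from the empty graph, single-edge moves (add, delete, reverse)
    that keep the graph acyclic and avoid the banned set are applied while
    they improve the decomposable score. After each local optimum the
    current best DAG is perturbed by ``perturb_moves`` random legal moves
    and re-climbed; the best DAG over all ``restarts`` rounds is returned.
    Deterministic for a fixed seed.
    """
    config = config or SearchConfig()
    banned = (
        constraints.banned_edges(data.variables) if constraints else set()
    )
    cache = _ScoreCache(data, config)
    rng = np.random.default_rng(config.seed)

    dag = Dag.from_edges(data.variables)
    best_dag, best_score, trace = _hill_climb(cache, dag, banned, config.max_iter)
    full_trace = list(trace)
    for _ in range(config.restarts - 1):
        perturbed = best_dag
        for _ in range(config.perturb_moves):
            moves = _legal_moves(perturbed, banned)
            if not moves:
                break
            perturbed = _apply_move(
                perturbed, moves[rng.integers(len(moves))]
            )
        dag, score, trace = _hill_climb(cache, perturbed, banned, config.max_iter)
        full_trace.extend(trace)
        if score > best_score + 1e-12:
            best_dag, best_score = dag, score

    fit = fit_network(data, best_dag, config)
    fit.score_trace = full_trace
    return fit


def enumerate_dags(nodes: Sequence[str]) -> list[Dag]:
    """All DAGs over a small node set (exhaustive; 25 DAGs for 3 nodes).

    Intended as an exact-search oracle for problems of at most ~4 nodes.
    """
    nodes = tuple(nodes)
    pairs = [
        (u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]
    ]
    dags = []
    # each unordered pair is absent, forward, or backward: 3^(p choose 2)
    for code in range(3 ** len(pairs)):
        edges = []
        c = code
        for u, v in pairs:
            c, state = divmod(c, 3)
            if state == 1:
                edges.append((u, v))
            elif state == 2:
                edges.append((v, u))
        try:
            dags.append(Dag.from_edges(nodes, edges))
        except ValueError:
            continue
    return dags


def exhaustive_search(
    data: AnalysisMatrix,
    constraints: TierConstraints | None = None,
    config: SearchConfig | None = None,
) -> tuple[Dag, float]:
    """Globally optimal DAG by enumeration (small node sets only)."""
    config = config or SearchConfig()
    cache = _ScoreCache(data, config)
    banned = (
        constraints.banned_edges(data.variables) if constraints else set()
    )
    best, best_score = None, -math.inf
    for dag in enumerate_dags(data.variables):
        if any(e in banned for e in dag.edges):
            continue
        score = sum(cache.family_score(v, dag.parents(v)) for v in dag.nodes)
        if score > best_score:
            best, best_score = dag, score
    return best, best_score
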