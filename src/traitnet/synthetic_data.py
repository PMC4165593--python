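"""Synthetic study data: linear-Gaussian SEM tables and toy censuses.

Real inputs for this analysis are a 53-species table of demographic rates
and functional traits, and the yearly tree censuses the rates derive from.
Neither is bundled here, so this module generates both from known ground
truth:

* :func:`simulate_sem` draws species-level tables from a linear-Gaussian
  structural equation model over a three-tier DAG, the generative
  counterpart of the per-node Gaussian linear models fitted by the network
  analysis. The implied covariance is available in closed form, so every
  estimator downstream can be checked against truth.
* :func:`simulate_census` produces individual-level yearly records (alive /
  recruited / dead, with DBH growth) with known per-year recruitment and
  mortality probabilities, to exercise the demographic-rate calculators.

:func:`default_paracou_like_spec` mirrors the qualitative structure of the
learned trait--demography network (four exogenous traits SV, WD, LNC, Dm;
recruitment driven positively by leaf phosphorus and negatively by wood
density and seed volume; mortality by maximum diameter; the population
change rate by the two demographic rates). Coefficients are standardized
defaults of magnitude 0.3--0.6 chosen to reproduce the sign pattern; they
are not estimates from any real dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gaussian_bn import AnalysisMatrix, Dag

DEFAULT_TIERS: dict[str, str] = {
    "SLA": "trait",
    "LNC": "trait",
    "LPC": "trait",
    "d13C": "trait",
    "WD": "trait",
    "Dm": "trait",
    "SV": "trait",
    "RDIR": "trait",
    "rec": "demographic",
    "mort": "demographic",
    "lambda": "performance",
}


@dataclass(frozen=True)
class SemSpec:
    """A linear-Gaussian structural equation model over a DAG."""

    dag: Dag
    intercepts: dict[str, float]
    coefficients: dict[tuple[str, str], float]  # (parent, child) -> beta
    sigmas: dict[str, float]                    # residual s.d. per node
    n: int = 53
    seed: int = 0
    tiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (p, c) in self.coefficients:
            if (p, c) not in self.dag.edges:
                raise ValueError(f"coefficient for non-edge ({p}, {c})")
        for v, s in self.sigmas.items():
            if s <= 0:
                raise ValueError(f"residual sd for {v!r} must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": list(self.dag.nodes),
                "edges": sorted(map(list, self.dag.edges)),
                "intercepts": self.intercepts,
                "coefficients": {
                    f"{p}->{c}": b for (p, c), b in sorted(self.coefficients.items())
                },
                "sigmas": self.sigmas,
                "n": self.n,
                "seed": self.seed,
                "tiers": self.tiers,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SemSpec":
        obj = json.loads(text)
        coef = {}
        for key, b in obj["coefficients"].items():
            p, c = key.split("->")
            coef[(p, c)] = float(b)
        return cls(
            dag=Dag.from_edges(obj["nodes"], [tuple(e) for e in obj["edges"]]),
            intercepts={k: float(v) for k, v in obj["intercepts"].items()},
            coefficients=coef,
            sigmas={k: float(v) for k, v in obj["sigmas"].items()},
            n=int(obj["n"]),
            seed=int(obj["seed"]),
            tiers=dict(obj.get("tiers", {})),
        )


def implied_covariance(spec: SemSpec) -> pd.DataFrame:
    """Closed-form covariance (I - B)^-1 S_eps (I - B)^-T of the SEM."""
    nodes = list(spec.dag.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    B = np.zeros((len(nodes), len(nodes)))
    for (p, c), b in spec.coefficients.items():
        B[idx[c], idx[p]] = b
    A = np.linalg.inv(np.eye(len(nodes)) - B)
    S_eps = np.diag([spec.sigmas[v] ** 2 for v in nodes])
    return pd.DataFrame(A @ S_eps @ A.T, index=nodes, columns=nodes)


def simulate_sem(
    spec: SemSpec, n: int | None = None, seed: int | None = None
) -> AnalysisMatrix:
    """Sample a species-level table from the SEM.

    Nodes are drawn in topological order as
    ``X_v = m_v + sum_p beta_vp X_p + eps_v`` with independent Gaussian
    noise. Deterministic for a fixed seed.
    """
    n = spec.n if n is None else n
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    order = spec.dag.topological_order()
    cols: dict[str, np.ndarray] = {}
    for v in order:
        x = np.full(n, spec.intercepts.get(v, 0.0))
        for p in spec.dag.parents(v):
            x = x + spec.coefficients[(p, v)] * cols[p]
        cols[v] = x + rng.normal(0.0, spec.sigmas[v], size=n)
    data = pd.DataFrame({v: cols[v] for v in spec.dag.nodes})
    tiers = spec.tiers or {v: "trait" for v in spec.dag.nodes}
    return AnalysisMatrix(data=data, tiers=tiers)


def _standardized_spec(
    nodes: list[str],
    edges_with_beta: dict[tuple[str, str], float],
    tiers: dict[str, str],
    n: int,
    seed: int,
) -> SemSpec:
    """Build a SemSpec whose nodes all have unit marginal variance by
    solving for each residual variance from the implied parent covariance."""
    dag = Dag.from_edges(nodes, edges_with_beta.keys())
    order = dag.topological_order()
    idx = {v: i for i, v in enumerate(order)}
    cov = np.zeros((len(order), len(order)))
    sigmas: dict[str, float] = {}
    for v in order:
        parents = dag.parents(v)
        i = idx[v]
        if not parents:
            sigmas[v] = 1.0
            cov[i, i] = 1.0
            continue
        pidx = [idx[p] for p in parents]
        beta = np.array([edges_with_beta[(p, v)] for p in parents])
        var_from_parents = float(beta @ cov[np.ix_(pidx, pidx)] @ beta)
        resid = 1.0 - var_from_parents
        if resid <= 0:
            raise ValueError(
                f"coefficients into {v!r} imply variance >= 1; reduce them"
            )
        sigmas[v] = float(np.sqrt(resid))
        cov[i, i] = 1.0
        # covariance of v with every earlier node
        for w in order[: order.index(v)]:
            j = idx[w]
            cov[i, j] = cov[j, i] = float(
                sum(b * cov[idx[p], j] for p, b in zip(parents, beta))
            )
    return SemSpec(
        dag=dag,
        intercepts={v: 0.0 for v in nodes},
        coefficients=dict(edges_with_beta),
        sigmas=sigmas,
        n=n,
        seed=seed,
        tiers={v: tiers[v] for v in nodes},
    )


def default_paracou_like_spec(
    n: int = 53, seed: int = 0, include_rdir: bool = False
) -> SemSpec:
    """Default ten-node SEM mirroring the trait--demography network.

    Exogenous: SV, WD, LNC, Dm. Sign pattern: LPC -> rec positive; WD -> rec
    and SV -> rec negative; mort <- Dm negative; lambda <- rec positive and
    <- mort negative. With ``include_rdir`` the direct WD -> rec edge is
    replaced by the mediated path WD -> RDIR -> rec (growth potential
    carrying the wood-density signal into recruitment).
    """
    betas: dict[tuple[str, str], float] = {
        ("WD", "LPC"): -0.45,
        ("LNC", "LPC"): 0.55,
        ("LPC", "d13C"): 0.45,
        ("Dm", "d13C"): 0.40,
        ("LNC", "SLA"): 0.50,
        ("d13C", "SLA"): -0.35,
        ("LPC", "rec"): 0.50,
        ("WD", "rec"): -0.40,
        ("SV", "rec"): -0.30,
        ("Dm", "mort"): -0.50,
        ("rec", "lambda"): 0.60,
        ("mort", "lambda"): -0.35,
    }
    nodes = ["SV", "WD", "LNC", "Dm", "LPC", "d13C", "SLA", "rec", "mort", "lambda"]
    if include_rdir:
        del betas[("WD", "rec")]
        betas[("WD", "RDIR")] = -0.55
        betas[("RDIR", "rec")] = 0.50
        nodes.insert(4, "RDIR")
    tiers = {v: DEFAULT_TIERS[v] for v in nodes}
    return _standardized_spec(nodes, betas, tiers, n=n, seed=seed)


# ---------------------------------------------------------------------------
# Toy censuses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensusSpec:
    """Parameters of a toy single-species yearly census.

    Defaults give a stand of 1000 trees followed 1992--2003 (11 annual
    intervals) with a 5% yearly per-capita recruitment probability and a 1%
    yearly mortality probability, roughly the magnitudes seen in disturbed
    tropical plots.
    """

    n_trees: int = 1000
    year_start: int = 1992
    n_years: int = 12          # census years; intervals = n_years - 1
    recruit_prob: float = 0.05
    mortality_prob: float = 0.01
    dbh_meanlog: float = 1.5   # initial DBH = 10 cm + lognormal(meanlog, sdlog)
    dbh_sdlog: float = 0.8
    growth_mean: float = 0.02  # yearly relative diameter increment
    growth_sd: float = 0.01
    excluded_fraction: float = 0.0
    species_id: str = "SP1"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.recruit_prob, self.mortality_prob, self.excluded_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_years < 2:
            raise ValueError("need at least two census years")


def simulate_census(spec: CensusSpec) -> pd.DataFrame:
    """Simulate a yearly census table (tree_id, species_id, year, dbh,
    status, excluded).

    Each year every living tree dies with probability ``mortality_prob``
    (recorded as a ``dead`` row the following year), survivors grow by a
    Gaussian relative increment, and ``Binomial(N_t, recruit_prob)`` new
    trees enter at the 10 cm threshold (recorded as ``recruited`` in their
    first year). A fraction of trees is flagged ``excluded`` at creation,
    standing in for trees wounded or poisoned by silvicultural operations.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    years = list(range(spec.year_start, spec.year_start + spec.n_years))
    next_id = 0

    def new_tree(recruit: bool) -> dict:
        nonlocal next_id
        next_id += 1
        dbh = (
            10.0 * (1.0 + rng.uniform(0.0, 0.03))
            if recruit
            else 10.0 + rng.lognormal(spec.dbh_meanlog, spec.dbh_sdlog)
        )
        return {
            "id": f"t{next_id:05d}",
            "dbh": float(dbh),
            "excluded": bool(rng.random() < spec.excluded_fraction),
            "recruit_year": years[0] if not recruit else None,
        }

    alive = [new_tree(recruit=False) for _ in range(spec.n_trees)]
    rows = []
    for tree in alive:
        rows.append((tree["id"], years[0], tree["dbh"], "alive", tree["excluded"]))

    for t, year in enumerate(years[:-1]):
        nxt = years[t + 1]
        n_alive = len(alive)
        survivors = []
        for tree in alive:
            if rng.random() < spec.mortality_prob:
                rows.append((tree["id"], nxt, tree["dbh"], "dead", tree["excluded"]))
            else:
                growth = rng.normal(spec.growth_mean, spec.growth_sd)
                tree["dbh"] *= max(1.0, 1.0 + growth)
                rows.append(
                    (tree["id"], nxt, tree["dbh"], "alive", tree["excluded"])
                )
                survivors.append(tree)
        n_recruits = int(rng.binomial(n_alive, spec.recruit_prob)) if n_alive else 0
        for _ in range(n_recruits):
            tree = new_tree(recruit=True)
            rows.append((tree["id"], nxt, tree["dbh"], "recruited", tree["excluded"]))
            survivors.append(tree)
        alive = survivors

    census = pd.DataFrame(
        rows, columns=["tree_id", "year", "dbh", "status", "excluded"]
    )
    census.insert(1, "species_id", spec.species_id)
    return census.sort_values(["tree_id", "year"]).reset_index(drop=True)
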