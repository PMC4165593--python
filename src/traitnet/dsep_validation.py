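"""Conditional-independence validation and conservative pruning of a DAG.

A fitted network is an over-parametrized claim about the data: every
non-adjacent pair of variables should be independent given the union of
their parents (the basis set of the DAG), and every edge should carry a
detectable conditional association. This module tests both claim kinds with
partial correlations — Pearson for consistency with the linear-Gaussian
model, Spearman on ranks as a robustness check — combines the
independence-claim p-values into Fisher's C statistic for an overall
goodness-of-fit test, and removes edges whose association is
non-significant under BOTH coefficients after multiple-testing correction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gaussian_bn import AnalysisMatrix, Dag, NetworkFit, SearchConfig, fit_network


@dataclass(frozen=True)
class IndependenceClaim:
    """A conditional (in)dependence statement x _||_ y | cond read off a DAG."""

    x: str
    y: str
    cond: tuple[str, ...]
    kind: str = "independence"  # "independence" (implied) or "dependence" (edge)

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ValueError("claim variables must differ")
        if self.x in self.cond or self.y in self.cond:
            raise ValueError("conditioning set must exclude the claim pair")


@dataclass
class TestResult:
    claim: IndependenceClaim
    r_pearson: float
    p_pearson: float
    r_spearman: float
    p_spearman: float
    p_pearson_corrected: float = math.nan
    p_spearman_corrected: float = math.nan
    significant: bool | None = None


@dataclass
class ValidationReport:
    """Outcome of testing a DAG's conditional-independence content."""

    basis: list[IndependenceClaim]
    independence_results: list[TestResult]
    edge_results: list[TestResult]
    C: float
    df: int
    p_C: float
    removed_edges: list[tuple[str, str]]
    final_dag: Dag
    final_fit: NetworkFit | None = None
    alpha: float = 0.05
    correction: str = "holm"

    def claims_table(self) -> pd.DataFrame:
        rows = []
        for res in self.independence_results + self.edge_results:
            rows.append(
                {
                    "kind": res.claim.kind,
                    "x": res.claim.x,
                    "y": res.claim.y,
                    "cond": "|".join(res.claim.cond),
                    "r_pearson": res.r_pearson,
                    "p_pearson": res.p_pearson,
                    "p_pearson_corrected": res.p_pearson_corrected,
                    "r_spearman": res.r_spearman,
                    "p_spearman": res.p_spearman,
                    "p_spearman_corrected": res.p_spearman_corrected,
                    "significant": res.significant,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "fisher_C": self.C,
                "df": self.df,
                "p_C": self.p_C,
                "alpha": self.alpha,
                "correction": self.correction,
                "removed_edges": sorted(map(list, self.removed_edges)),
                "final_edges": sorted(map(list, self.final_dag.edges)),
                "claims": self.claims_table().to_dict(orient="records"),
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Graphical criteria
# ---------------------------------------------------------------------------

def d_separated(dag: Dag, x: str, y: str, cond=()) -> bool:
    """True iff every path between x and y is blocked given ``cond``."""
    for v in (x, y, *cond):
        if v not in dag.nodes:
            raise ValueError(f"unknown variable {v!r}")
    if x == y:
        raise ValueError("x and y must differ")
    return nx.is_d_separator(dag.to_networkx(), {x}, {y}, set(cond))


def basis_set(dag: Dag) -> list[IndependenceClaim]:
    """Union-of-parents basis set of a DAG.

    For every non-adjacent pair taken in a fixed topological order (so the
    second variable is never an ancestor of the first), emit the claim
    x _||_ y | pa(x) u pa(y). Each claim is d-separated in the DAG, and
    together they summarize its full testable independence content.
    """
    order = dag.topological_order()
    claims = []
    for i, x in enumerate(order):
        for y in order[i + 1 :]:
            if dag.adjacent(x, y):
                continue
            cond = tuple(
                sorted((set(dag.parents(x)) | set(dag.parents(y))) - {x, y})
            )
            claims.append(IndependenceClaim(x=x, y=y, cond=cond))
    return claims


# ---------------------------------------------------------------------------
# Partial correlation and tests
# ---------------------------------------------------------------------------

def partial_correlation(
    R: pd.DataFrame | np.ndarray, x, y, cond=()
) -> float:
    """Partial correlation of x and y given ``cond`` by the classical
    recursion on a correlation matrix:

        r_xy.Zw = (r_xy.Z - r_xw.Z * r_yw.Z) / sqrt((1-r_xw.Z^2)(1-r_yw.Z^2))

    Memoized over subproblems; equals the precision-matrix expression
    -P_xy / sqrt(P_xx P_yy) for any positive-definite R.
    """
    if isinstance(R, pd.DataFrame):
        names = {v: i for i, v in enumerate(R.columns)}
        Rm = R.to_numpy(dtype=float)
        x, y = names[x], names[y]
        cond = tuple(names[c] for c in cond)
    else:
        Rm = np.asarray(R, dtype=float)
        cond = tuple(cond)
    if x == y or x in cond or y in cond:
        raise ValueError("claim pair must be distinct and outside cond")

    memo: dict[tuple[int, int, frozenset], float] = {}

    def rec(a: int, b: int, z: frozenset) -> float:
        if a > b:
            a, b = b, a
        key = (a, b, z)
        if key in memo:
            return memo[key]
        if not z:
            val = float(Rm[a, b])
        else:
            w = max(z)
            rest = z - {w}
            r_ab = rec(a, b, rest)
            r_aw = rec(a, w, rest)
            r_bw = rec(b, w, rest)
            denom_sq = (1.0 - r_aw**2) * (1.0 - r_bw**2)
            if denom_sq <= 0:
                raise ValueError(
                    "undefined partial correlation: perfect collinearity "
                    "with a conditioning variable"
                )
            val = (r_ab - r_aw * r_bw) / math.sqrt(denom_sq)
        memo[key] = val
        return val

    return rec(x, y, frozenset(cond))


def ci_test(
    data: AnalysisMatrix | pd.DataFrame,
    claim: IndependenceClaim,
    coefficient: str = "pearson",
) -> tuple[float, float]:
    """Partial-correlation conditional-independence test.

    Pearson runs the recursion on the data correlation matrix; Spearman runs
    the same recursion on the correlation matrix of the rank-transformed
    data. The p-value comes from Fisher's z transform,
    z = atanh(r) * sqrt(n - |cond| - 3), referred to a standard normal
    (two-sided).
    """
    df = data.data if isinstance(data, AnalysisMatrix) else data
    cols = [claim.x, claim.y, *claim.cond]
    sub = df[cols].to_numpy(dtype=float)
    n, k = sub.shape[0], len(claim.cond)
    if n <= k + 3:
        raise ValueError(f"untestable claim: n={n} too small for |cond|={k}")
    if coefficient == "spearman":
        sub = np.apply_along_axis(stats.rankdata, 0, sub)
    elif coefficient != "pearson":
        raise ValueError(f"unknown coefficient {coefficient!r}")
    R = np.corrcoef(sub, rowvar=False)
    r = partial_correlation(R, 0, 1, tuple(range(2, 2 + k)))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    z = math.atanh(r) * math.sqrt(n - k - 3)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(r), float(p)


def fisher_c(pvalues) -> tuple[float, int, float]:
    """Fisher's C over k independence-claim p-values: C = -2 sum(ln p),
    chi-square distributed with 2k degrees of freedom when every claim
    holds."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    C = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return C, df, float(stats.chi2.sf(C, df))


# ---------------------------------------------------------------------------
# Validation and pruning
# ---------------------------------------------------------------------------

def _run_tests(data, claims, coefficient):
    return [ci_test(data, c, coefficient) for c in claims]


def _correct(pvals: list[float], method: str) -> list[float]:
    if not pvals:
        return []
    mapping = {"holm": "holm", "bh": "fdr_bh", "fdr_bh": "fdr_bh"}
    if method not in mapping:
        raise ValueError(f"unknown correction {method!r}")
    return list(multipletests(pvals, method=mapping[method])[1])


def validate_and_prune(
    data: AnalysisMatrix,
    dag: Dag,
    alpha: float = 0.05,
    correction: str = "holm",
    config: SearchConfig | None = None,
) -> ValidationReport:
    """Test a learned DAG's independence content and prune weak edges.

    Every basis-set independence claim is tested with both coefficients and
    summarized by Fisher's C (computed over the Pearson p-values). Every
    edge u -> v is tested as the dependence claim u ~ v | pa(v) \\ {u}; the
    edge is removed iff its corrected p-values are non-significant for BOTH
    coefficients — a conservative rule that only ever deletes edges.
    P-value corrections are applied separately per coefficient and per
    claim kind. The pruned DAG is refit before returning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    claims = basis_set(dag)
    ind_results = []
    for claim in claims:
        rp, pp = ci_test(data, claim, "pearson")
        rs, ps = ci_test(data, claim, "spearman")
        ind_results.append(
            TestResult(claim=claim, r_pearson=rp, p_pearson=pp,
                       r_spearman=rs, p_spearman=ps)
        )
    if ind_results:
        for res, pc in zip(
            ind_results, _correct([r.p_pearson for r in ind_results], correction)
        ):
            res.p_pearson_corrected = pc
        for res, pc in zip(
            ind_results, _correct([r.p_spearman for r in ind_results], correction)
        ):
            res.p_spearman_corrected = pc
        C, dof, p_C = fisher_c(
            [max(r.p_pearson, 1e-300) for r in ind_results]
        )
    else:
        C, dof, p_C = 0.0, 0, 1.0

    edge_results = []
    for u, v in sorted(dag.edges):
        cond = tuple(p for p in dag.parents(v) if p != u)
        claim = IndependenceClaim(x=u, y=v, cond=cond, kind="dependence")
        rp, pp = ci_test(data, claim, "pearson")
        rs, ps = ci_test(data, claim, "spearman")
        edge_results.append(
            TestResult(claim=claim, r_pearson=rp, p_pearson=pp,
                       r_spearman=rs, p_spearman=ps)
        )
    for res, pc in zip(
        edge_results, _correct([r.p_pearson for r in edge_results], correction)
    ):
        res.p_pearson_corrected = pc
    for res, pc in zip(
        edge_results, _correct([r.p_spearman for r in edge_results], correction)
    ):
        res.p_spearman_corrected = pc

    removed = []
    final = dag
    for res in edge_results:
        res.significant = (
            res.p_pearson_corrected < alpha or res.p_spearman_corrected < alpha
        )
        if not res.significant:
            edge = (res.claim.x, res.claim.y)
            removed.append(edge)
            final = final.without_edge(*edge)

    final_fit = fit_network(data, final, config or SearchConfig())
    return ValidationReport(
        basis=claims,
        independence_results=ind_results,
        edge_results=edge_results,
        C=C,
        df=dof,
        p_C=p_C,
        removed_edges=removed,
        final_dag=final,
        final_fit=final_fit,
        alpha=alpha,
        correction=correction,
    )
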