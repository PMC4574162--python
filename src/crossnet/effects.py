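"""Linear-Gaussian SEM parameter estimation on a learned DAG.

Once the structure is fully directed, each node's local distribution is
Gaussian with mean linear in its parents, so maximum likelihood reduces to
one ordinary-least-squares regression per node.  Effects of one variable
on another decompose over directed paths: the effect along a path is the
product of its edge coefficients, and the total effect is the sum over all
simple directed paths.  Structural stability is assessed by jackknife
resampling: the network is re-learned on every leave-one-out dataset and
each full-data edge is scored for presence and direction agreement.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .causalnet import PDAG, PriorKnowledge, apply_meek_rules

logger = logging.getLogger(__name__)

__all__ = [
    "extend_to_dag",
    "LinearSEM",
    "LinearSEMResults",
    "fit_ml",
    "enumerate_paths",
    "PathDecomposition",
    "total_effect",
    "StabilityReport",
    "jackknife_stability",
]


def extend_to_dag(
    pdag: PDAG, prior: PriorKnowledge | None = None, best_effort: bool = False
) -> PDAG:
    """Resolve remaining undirected edges into a consistent DAG.

    Prior (whitelist / genotype-exogenous) orientations are applied first
    and propagated; any leftover undirected edges are oriented with the
    Dor-Tarsi consistent-extension algorithm, which guarantees no new
    v-structures and no directed cycles whenever an extension exists.
    Raises ``ValueError`` listing the blocking edges otherwise.

    A finite-sample skeleton can be genuinely inextensible (e.g. a
    chordless cycle with no declared collider admits no acyclic
    orientation without a new v-structure).  With ``best_effort=True``
    the remaining edges are then oriented acyclically anyway (new
    v-structures permitted, logged as a warning) so that parameters can
    still be estimated.
    """
    out = pdag.copy()
    from .causalnet import _apply_prior_orientations

    _apply_prior_orientations(out, prior)
    apply_meek_rules(out, prior)
    if out.fully_directed():
        out.validate(prior)
        return out

    # Dor-Tarsi on a working copy; orientations found there are replayed
    # onto `out` so directed edges already fixed are preserved.
    work = out.copy()
    remaining = set(work.nodes)
    while remaining:
        progressed = False
        for x in sorted(remaining):
            out_deg = any(
                work.has_directed(x, y) for y in work.neighbors(x) if y in remaining
            )
            if out_deg:
                continue
            undir_nb = [
                y
                for y in work.neighbors(x)
                if y in remaining and work.has_undirected(x, y)
            ]
            all_nb = [y for y in work.neighbors(x) if y in remaining]
            ok = all(
                work.adjacent(y, z)
                for y in undir_nb
                for z in all_nb
                if z != y
            )
            if not ok:
                continue
            for y in undir_nb:
                work.orient(y, x)
                out.orient(y, x)
            remaining.discard(x)
            progressed = True
            break
        if not progressed:
            blocking = [e for e in out.undirected_edges]
            if not best_effort:
                raise ValueError(
                    f"no consistent extension; blocking undirected edges: {blocking}"
                )
            logger.warning(
                "no consistent extension; orienting %d edges acyclically "
                "(new v-structures permitted): %s",
                len(blocking),
                blocking,
            )
            for a, b in blocking:
                if not out.has_undirected(a, b):
                    continue
                first, second = sorted((a, b))
                if prior is not None and prior.forbidden(first, second):
                    first, second = second, first
                if out.creates_cycle(first, second):
                    first, second = second, first
                out.orient(first, second)
                apply_meek_rules(out, prior)
            break
    out.validate(prior)
    return out


# ---------------------------------------------------------------------------
# ML fitting


@dataclass
class LinearSEMResults:
    """Edge coefficients, intercepts and residual variances of a fitted DAG.

    ``params`` has one row per edge: parent, child, coefficient, OLS
    standard error.  ``node_stats`` has one row per node: intercept and the
    maximum-likelihood residual variance (divisor ``n``).
    """

    graph: nx.DiGraph
    params: pd.DataFrame
    node_stats: pd.DataFrame
    n: int

    def coefficient(self, parent: str, child: str) -> float:
        m = self.params[(self.params["parent"] == parent) & (self.params["child"] == child)]
        if len(m) == 0:
            raise KeyError(f"no edge {parent} -> {child}")
        return float(m["coef"].iloc[0])

    def total_effect(self, source: str, sink: str) -> "PathDecomposition":
        return total_effect(self, source, sink)

    def summary(self) -> str:
        lines = [
            f"Linear-Gaussian SEM, ML fit (n = {self.n})",
            f"{'parent':<12}{'child':<12}{'coef':>10}{'se':>10}",
        ]
        for _, r in self.params.iterrows():
            lines.append(
                f"{r['parent']:<12}{r['child']:<12}{r['coef']:>10.4f}{r['se']:>10.4f}"
            )
        lines.append("")
        lines.append(f"{'node':<12}{'intercept':>10}{'resid_var':>10}")
        for _, r in self.node_stats.iterrows():
            lines.append(
                f"{r['node']:<12}{r['intercept']:>10.4f}{r['resid_var']:>10.4f}"
            )
        return "\n".join(lines)


class LinearSEM:
    """Model object tying a fully directed DAG to a dataset.

    ``fit`` performs node-wise OLS (equal to maximum likelihood for
    linear-Gaussian local distributions) and returns
    :class:`LinearSEMResults`.
    """

    def __init__(self, dag, data: pd.DataFrame):
        self.graph = _as_digraph(dag)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("structure must be a DAG")
        missing = [v for v in self.graph.nodes if v not in data.columns]
        if missing:
            raise ValueError(f"data lacks columns for nodes: {missing}")
        self.data = data

    def fit(self) -> LinearSEMResults:
        n = len(self.data)
        edge_rows, node_rows = [], []
        for v in self.graph.nodes:
            parents = sorted(self.graph.predecessors(v))
            if n < len(parents) + 2:
                raise ValueError(f"too few observations to fit node {v!r}")
            y = self.data[v].to_numpy(dtype=float)
            X = np.column_stack(
                [np.ones(n)]
                + [self.data[p].to_numpy(dtype=float) for p in parents]
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(f"collinear parents for node {v!r}: {parents}")
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            rss = float(resid @ resid)
            df = n - X.shape[1]
            s2_ols = rss / df if df > 0 else np.nan
            xtx_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(np.maximum(np.diag(xtx_inv) * s2_ols, 0.0))
            for j, p in enumerate(parents, start=1):
                edge_rows.append(
                    {"parent": p, "child": v, "coef": float(beta[j]), "se": float(se[j])}
                )
            node_rows.append(
                {
                    "node": v,
                    "intercept": float(beta[0]),
                    "resid_var": rss / n,  # ML divisor
                }
            )
        g = self.graph.copy()
        for row in edge_rows:
            g.edges[row["parent"], row["child"]]["coef"] = row["coef"]
            g.edges[row["parent"], row["child"]]["se"] = row["se"]
        return LinearSEMResults(
            graph=g,
            params=pd.DataFrame(edge_rows, columns=["parent", "child", "coef", "se"]),
            node_stats=pd.DataFrame(node_rows, columns=["node", "intercept", "resid_var"]),
            n=n,
        )


def _as_digraph(dag) -> nx.DiGraph:
    if isinstance(dag, nx.DiGraph):
        return dag.copy()
    if isinstance(dag, PDAG):
        if not dag.fully_directed():
            raise ValueError(
                "PDAG has undirected edges; resolve with extend_to_dag first"
            )
        return dag.directed_graph()
    g = nx.DiGraph()
    g.add_edges_from(dag)
    return g


def fit_ml(dag, data: pd.DataFrame) -> LinearSEMResults:
    """Functional wrapper: node-wise OLS ML fit of a fully directed DAG."""
    return LinearSEM(dag, data).fit()


# ---------------------------------------------------------------------------
# Path decomposition


def enumerate_paths(dag, source: str, sink: str) -> list:
    """All simple directed paths from ``source`` to ``sink``, DFS order.

    ``source == sink`` returns the empty list by convention (a DAG has no
    cycles, so there is no non-trivial path from a node to itself).
    """
    g = _as_digraph(dag)
    for v in (source, sink):
        if v not in g.nodes:
            raise KeyError(f"node {v!r} not in graph")
    if source == sink:
        return []
    paths = []

    def dfs(node, trail):
        if node == sink:
            paths.append(tuple(trail))
            return
        for nxt in sorted(g.successors(node)):
            if nxt not in trail:
                dfs(nxt, trail + [nxt])

    dfs(source, [source])
    return paths


@dataclass(frozen=True)
class PathDecomposition:
    source: str
    sink: str
    paths: tuple  # tuples of node names
    path_effects: tuple  # product of edge coefficients per path
    total: float  # sum of path effects

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [" -> ".join(p) for p in self.paths],
                "effect": self.path_effects,
            }
        )


def total_effect(fitted: LinearSEMResults, source: str, sink: str) -> PathDecomposition:
    """Sum over all directed simple paths of the product of coefficients.

    For a linear SEM with exogenous source this equals the population
    regression slope of the sink on the source alone.
    """
    g = fitted.graph
    paths = enumerate_paths(g, source, sink)
    effects = []
    for p in paths:
        e = 1.0
        for a, b in zip(p[:-1], p[1:]):
            e *= g.edges[a, b]["coef"]
        effects.append(e)
    return PathDecomposition(
        source=source,
        sink=sink,
        paths=tuple(paths),
        path_effects=tuple(effects),
        total=float(sum(effects)),
    )


# ---------------------------------------------------------------------------
# Jackknife stability


@dataclass
class StabilityReport:
    """Leave-one-out stability of every full-data adjacency.

    ``table`` rows: edge endpoints (in the full-data orientation, or sorted
    for undirected edges), the full-data state, presence frequency over the
    resampled networks, and — among resamples where the adjacency is
    present — the fractions recovered in the same state, the opposite
    direction, or undirected.
    """

    table: pd.DataFrame
    reference: PDAG
    n_resamples: int
    n_failed: int

    def summary(self) -> pd.DataFrame:
        return self.table


def _edge_state(pdag: PDAG, a: str, b: str) -> str | None:
    if pdag.has_directed(a, b):
        return "->"
    if pdag.has_directed(b, a):
        return "<-"
    if pdag.has_undirected(a, b):
        return "--"
    return None


def jackknife_stability(
    data: pd.DataFrame,
    learner: Callable[[pd.DataFrame], PDAG],
    reference: PDAG | None = None,
) -> StabilityReport:
    """Leave-one-out re-learning of the network structure.

    ``learner`` maps a dataset to a PDAG with fixed settings.  For each of
    the ``n`` leave-one-out datasets the structure is re-learned; every
    adjacency of the full-data network is scored for presence and, among
    resamples where it is present, for direction agreement (same state /
    opposite direction / undirected).  A learner failure on a resample is
    logged and excluded from the denominator.
    """
    n = len(data)
    if n < 10:
        raise ValueError("jackknife needs n >= 10")
    ref = reference if reference is not None else learner(data)
    edges = [(a, b) for a, b in ref.directed_edges] + list(ref.undirected_edges)
    counts = {e: {"present": 0, "same": 0, "opposite": 0, "undirected": 0} for e in edges}
    n_failed = 0
    n_ok = 0
    for i in range(n):
        sub = data.drop(index=data.index[i])
        try:
            g = learner(sub)
        except Exception as exc:  # noqa: BLE001 - any learner failure counts
            logger.warning("jackknife resample %d failed: %s", i, exc)
            n_failed += 1
            continue
        n_ok += 1
        for a, b in edges:
            state = _edge_state(g, a, b)
            if state is None:
                continue
            c = counts[(a, b)]
            c["present"] += 1
            ref_state = _edge_state(ref, a, b)
            if state == ref_state:
                c["same"] += 1
            elif state == "--":
                c["undirected"] += 1
            else:
                c["opposite"] += 1
    rows = []
    for (a, b), c in counts.items():
        present = c["present"]
        rows.append(
            {
                "a": a,
                "b": b,
                "state": _edge_state(ref, a, b),
                "presence": present / n_ok if n_ok else np.nan,
                "same": c["same"] / present if present else np.nan,
                "opposite": c["opposite"] / present if present else np.nan,
                "undirected": c["undirected"] / present if present else np.nan,
            }
        )
    return StabilityReport(
        table=pd.DataFrame(
            rows, columns=["a", "b", "state", "presence", "same", "opposite", "undirected"]
        ),
        reference=ref,
        n_resamples=n_ok,
        n_failed=n_failed,
    )
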