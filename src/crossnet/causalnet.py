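"""Constraint-based causal structure learning over Gaussian variables.

Conditional independence of (adjusted) traits is judged with Fisher's Z
test on partial correlations.  Two learners are provided: the Inductive
Causation (IC) algorithm, an exhaustive reference that searches all
separating sets, and the Incremental Association Markov Blanket (IAMB)
algorithm, which first learns each variable's Markov blanket and then
restricts separating-set searches to the blankets.  Both return a
partially directed acyclic graph (PDAG): v-structures identified from the
data are directed, the remaining edges are oriented as far as possible by
Meek's propagation rules without creating new v-structures or cycles.

Prior knowledge enters as constraints: a whitelist of required directed
edges, a blacklist of forbidden edges or directions, and the default
"genotype-exogenous" rule that nothing may point into a genotype node
(a QTL genotype is fixed at conception, so traits cannot cause it).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CITestResult",
    "CITester",
    "partial_correlation",
    "fisher_z",
    "fisher_z_test",
    "PriorKnowledge",
    "PDAG",
    "ic_algorithm",
    "iamb_markov_blanket",
    "learn_structure_iamb",
    "adjust_phenotypes",
    "adjust_expression",
]


# ---------------------------------------------------------------------------
# Conditional independence testing


def fisher_z(rho: float, n: int, n_cond: int) -> float:
    """Fisher Z statistic for a partial correlation ``rho`` estimated from
    ``n`` observations given ``n_cond`` conditioning variables:
    ``Z = 0.5 * sqrt(n - n_cond - 3) * log((1 + rho) / (1 - rho))``,
    approximately N(0, 1) under conditional independence."""
    return float(
        0.5 * np.sqrt(n - n_cond - 3) * np.log((1 + rho) / (1 - rho))
    )


@dataclass(frozen=True)
class CITestResult:
    x: str
    y: str
    w: tuple
    rho: float
    z: float
    p: float
    n: int

    @property
    def independent(self) -> bool:
        return bool(self.p > self._alpha)

    _alpha: float = 0.05


class CITester:
    """Caches the sample correlation matrix for repeated partial-correlation
    tests on the same dataset."""

    def __init__(self, data: pd.DataFrame):
        X = data.to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("data contains non-finite values")
        sd = X.std(axis=0)
        if (sd < 1e-12).any():
            bad = [c for c, s in zip(data.columns, sd) if s < 1e-12]
            raise ValueError(f"constant columns: {bad}")
        self.columns = list(data.columns)
        self.n = len(data)
        self.corr = np.corrcoef(X, rowvar=False)
        self._idx = {c: i for i, c in enumerate(self.columns)}

    def partial_correlation(self, x: str, y: str, w: Sequence[str] = ()) -> float:
        """Partial correlation of ``x`` and ``y`` given ``w`` via inversion
        of the correlation submatrix (precision-matrix formula)."""
        if x == y:
            raise ValueError("x and y must differ")
        w = tuple(w)
        if x in w or y in w:
            raise ValueError("conditioning set must exclude x and y")
        if self.n <= len(w) + 3:
            raise ValueError(
                f"need n > |W| + 3 (n = {self.n}, |W| = {len(w)})"
            )
        sel = [self._idx[x], self._idx[y]] + [self._idx[v] for v in w]
        sub = self.corr[np.ix_(sel, sel)]
        if not w:
            return float(np.clip(sub[0, 1], -1.0, 1.0))
        # Schur complement of the conditioning block (equivalent to the
        # precision-matrix formula, with explicit degeneracy diagnosis)
        K = sub[2:, 2:]
        if np.linalg.matrix_rank(K, tol=1e-10) < len(w):
            raise np.linalg.LinAlgError(
                f"collinear conditioning set: {list(w)}"
            )
        B = sub[:2, 2:]
        A = sub[:2, :2] - B @ np.linalg.solve(K, B.T)
        denom = A[0, 0] * A[1, 1]
        if denom <= 1e-24:
            raise np.linalg.LinAlgError(
                f"zero conditional variance for {x!r} or {y!r} given {list(w)}"
            )
        return float(np.clip(A[0, 1] / np.sqrt(denom), -1.0, 1.0))

    def test(self, x: str, y: str, w: Sequence[str] = (), alpha: float = 0.05) -> CITestResult:
        """Fisher Z test: ``Z = 0.5 sqrt(n - |W| - 3) log((1+r)/(1-r))``,
        approximately standard normal under conditional independence."""
        w = tuple(sorted(w))
        rho = self.partial_correlation(x, y, w)
        rho = float(np.clip(rho, -1.0, 1.0))
        if abs(rho) >= 1.0 - 1e-15:
            return CITestResult(x, y, w, rho, np.inf if rho > 0 else -np.inf, 0.0, self.n, alpha)
        z = fisher_z(rho, self.n, len(w))
        p = 2.0 * float(stats.norm.sf(abs(z)))
        return CITestResult(x, y, w, rho, z, p, self.n, alpha)


def partial_correlation(data: pd.DataFrame, x: str, y: str, w: Sequence[str] = ()) -> float:
    return CITester(data).partial_correlation(x, y, w)


def fisher_z_test(
    data: pd.DataFrame, x: str, y: str, w: Sequence[str] = (), alpha: float = 0.05
) -> CITestResult:
    return CITester(data).test(x, y, w, alpha=alpha)


# ---------------------------------------------------------------------------
# Graph containers and prior knowledge


@dataclass(frozen=True)
class PriorKnowledge:
    """Constraints applied during orientation.

    ``whitelist`` edges are required with the given direction;
    ``blacklist`` pairs are forbidden in the given direction (listing both
    directions removes the edge from the skeleton).  With
    ``genotype_exogenous`` (default) no edge may be directed into a node
    typed ``genotype``.
    """

    whitelist: tuple = ()
    blacklist: tuple = ()
    genotype_exogenous: bool = True

    def __post_init__(self) -> None:
        overlap = set(self.whitelist) & set(self.blacklist)
        if overlap:
            raise ValueError(f"whitelist and blacklist overlap: {sorted(overlap)}")

    def forbidden(self, a: str, b: str) -> bool:
        """True if the directed edge a -> b is disallowed."""
        return (a, b) in self.blacklist or (b, a) in self.whitelist

    def edge_excluded(self, a: str, b: str) -> bool:
        """True if the adjacency a - b is disallowed in both directions."""
        if (a, b) in self.whitelist or (b, a) in self.whitelist:
            return False
        return (a, b) in self.blacklist and (b, a) in self.blacklist


class PDAG:
    """Partially directed acyclic graph with typed nodes.

    Edges are either directed (``a -> b``) or undirected (``a -- b``);
    the directed part must stay acyclic and, under the default prior, no
    edge may point into a genotype node.
    """

    def __init__(self, nodes: Sequence[str], node_types: Mapping[str, str] | None = None):
        self.nodes = list(nodes)
        self.node_types = dict(node_types) if node_types else {v: "phenotype" for v in nodes}
        self._dir: set = set()
        self._undir: set = set()
        self.conflicts: list = []

    # -- basic structure -------------------------------------------------
    def add_undirected(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError("self-loops not allowed")
        key = frozenset((a, b))
        if (a, b) in self._dir or (b, a) in self._dir:
            raise ValueError(f"edge {a}-{b} already directed")
        self._undir.add(key)

    def add_directed(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError("self-loops not allowed")
        self._undir.discard(frozenset((a, b)))
        self._dir.add((a, b))

    def orient(self, a: str, b: str) -> None:
        """Turn the undirected edge a -- b into a -> b."""
        key = frozenset((a, b))
        if key not in self._undir:
            raise ValueError(f"no undirected edge {a}-{b}")
        self._undir.discard(key)
        self._dir.add((a, b))

    def unorient(self, a: str, b: str) -> None:
        self._dir.discard((a, b))
        self._dir.discard((b, a))
        self._undir.add(frozenset((a, b)))

    def remove_edge(self, a: str, b: str) -> None:
        self._undir.discard(frozenset((a, b)))
        self._dir.discard((a, b))
        self._dir.discard((b, a))

    # -- queries ---------------------------------------------------------
    def adjacent(self, a: str, b: str) -> bool:
        return (
            frozenset((a, b)) in self._undir
            or (a, b) in self._dir
            or (b, a) in self._dir
        )

    def has_directed(self, a: str, b: str) -> bool:
        return (a, b) in self._dir

    def has_undirected(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._undir

    def neighbors(self, a: str) -> list:
        out = set()
        for x, y in self._dir:
            if x == a:
                out.add(y)
            elif y == a:
                out.add(x)
        for e in self._undir:
            if a in e:
                out |= set(e) - {a}
        return sorted(out)

    @property
    def directed_edges(self) -> list:
        return sorted(self._dir)

    @property
    def undirected_edges(self) -> list:
        return sorted(tuple(sorted(e)) for e in self._undir)

    def directed_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self._dir)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.directed_graph())

    def creates_cycle(self, a: str, b: str) -> bool:
        """Would directing a -> b close a directed cycle?"""
        g = self.directed_graph()
        return g.has_edge(b, a) or nx.has_path(g, b, a)

    def fully_directed(self) -> bool:
        return not self._undir

    def copy(self) -> "PDAG":
        p = PDAG(self.nodes, self.node_types)
        p._dir = set(self._dir)
        p._undir = set(self._undir)
        p.conflicts = list(self.conflicts)
        return p

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PDAG)
            and set(self.nodes) == set(other.nodes)
            and self._dir == other._dir
            and self._undir == other._undir
        )

    def skeleton(self) -> set:
        return {frozenset((a, b)) for a, b in self._dir} | set(self._undir)

    def v_structures(self) -> set:
        """Unshielded colliders a -> c <- b (a, b non-adjacent)."""
        out = set()
        for (a, c) in self._dir:
            for (b, c2) in self._dir:
                if c2 == c and a < b and not self.adjacent(a, b):
                    out.add((a, c, b))
        return out

    def validate(self, prior: "PriorKnowledge | None" = None) -> None:
        if not self.is_acyclic():
            raise ValueError("directed subgraph contains a cycle")
        if prior is not None and prior.genotype_exogenous:
            for a, b in self._dir:
                if self.node_types.get(b) == "genotype":
                    raise ValueError(f"edge into genotype node: {a} -> {b}")


# ---------------------------------------------------------------------------
# Orientation machinery


def _can_orient(pdag: PDAG, a: str, b: str, prior: PriorKnowledge | None) -> bool:
    if prior is not None:
        if prior.forbidden(a, b):
            return False
        if prior.genotype_exogenous and pdag.node_types.get(b) == "genotype":
            return False
    return not pdag.creates_cycle(a, b)


def apply_meek_rules(pdag: PDAG, prior: PriorKnowledge | None = None) -> PDAG:
    """Orient undirected edges by Meek's rules R1-R4 until fixpoint.

    Only orientations that neither create a directed cycle nor violate the
    prior are applied; each rule fires only when the forced direction is
    admissible.
    """
    changed = True
    while changed:
        changed = False
        for a, b in list(pdag.undirected_edges) + [
            (b, a) for a, b in pdag.undirected_edges
        ]:
            if not pdag.has_undirected(a, b):
                continue
            if _meek_applies(pdag, a, b) and _can_orient(pdag, a, b, prior):
                pdag.orient(a, b)
                changed = True
    return pdag


def _meek_applies(pdag: PDAG, a: str, b: str) -> bool:
    """True if some Meek rule forces the orientation a -> b."""
    # R1: c -> a, a -- b, c and b non-adjacent  =>  a -> b
    for c in pdag.nodes:
        if c in (a, b):
            continue
        if pdag.has_directed(c, a) and not pdag.adjacent(c, b):
            return True
    # R2: a -> c -> b with a -- b  =>  a -> b
    for c in pdag.nodes:
        if c in (a, b):
            continue
        if pdag.has_directed(a, c) and pdag.has_directed(c, b):
            return True
    # R3: a -- c, a -- d, c -> b, d -> b, c and d non-adjacent  =>  a -> b
    into_b = [
        c
        for c in pdag.nodes
        if c not in (a, b) and pdag.has_directed(c, b) and pdag.has_undirected(a, c)
    ]
    for c, d in itertools.combinations(into_b, 2):
        if not pdag.adjacent(c, d):
            return True
    # R4: c -> d, d -> b, a adjacent to c and d, b and c non-adjacent => a -> b
    for d in pdag.nodes:
        if d in (a, b) or not pdag.has_directed(d, b) or not pdag.adjacent(a, d):
            continue
        for c in pdag.nodes:
            if c in (a, b, d):
                continue
            if (
                pdag.has_directed(c, d)
                and pdag.adjacent(a, c)
                and not pdag.adjacent(b, c)
            ):
                return True
    return False


def _apply_prior_orientations(pdag: PDAG, prior: PriorKnowledge | None) -> None:
    if prior is None:
        return
    for a, b in prior.whitelist:
        if pdag.has_undirected(a, b):
            pdag.orient(a, b)
        elif pdag.has_directed(b, a):
            pdag.conflicts.append(("whitelist", a, b))
            logger.warning("whitelist edge %s -> %s conflicts with learned direction", a, b)
            pdag.remove_edge(b, a)
            pdag.add_directed(a, b)
        elif not pdag.adjacent(a, b):
            pdag.add_directed(a, b)
    if prior.genotype_exogenous:
        for v in pdag.nodes:
            if pdag.node_types.get(v) != "genotype":
                continue
            for u in pdag.neighbors(v):
                if pdag.has_undirected(v, u):
                    pdag.orient(v, u)
                elif pdag.has_directed(u, v):
                    pdag.conflicts.append(("genotype-exogenous", u, v))
                    logger.warning("reversing learned edge %s -> %s into genotype", u, v)
                    pdag.remove_edge(u, v)
                    pdag.add_directed(v, u)


def _orient_v_structures(pdag: PDAG, collider_test, prior: PriorKnowledge | None) -> None:
    """Direct unshielded triples a - c - b as colliders when ``collider_test``
    says no separating set containing c exists; conflicting orientations
    leave the contested edges undirected and are logged."""
    proposals = []
    for c in pdag.nodes:
        nb = pdag.neighbors(c)
        for a, b in itertools.combinations(sorted(nb), 2):
            if pdag.adjacent(a, b):
                continue
            if collider_test(a, b, c):
                proposals.append((a, c, b))
    conflicted: set = set()
    for a, c, b in proposals:
        for x in (a, b):
            if pdag.has_directed(c, x):
                pdag.conflicts.append(("v-structure", x, c))
                logger.warning("conflicting v-structure orientation at %s - %s", x, c)
                conflicted.add(frozenset((x, c)))
                pdag.unorient(c, x)
            elif pdag.has_undirected(x, c) and frozenset((x, c)) not in conflicted:
                if _can_orient(pdag, x, c, prior):
                    pdag.orient(x, c)


# ---------------------------------------------------------------------------
# IC algorithm (exhaustive reference)


def _subsets(pool: Sequence[str], include: str | None = None):
    """All subsets of ``pool`` in deterministic (size, lexicographic) order,
    each containing ``include`` when given."""
    pool = sorted(pool)
    for size in range(len(pool) + 1):
        for s in itertools.combinations(pool, size):
            if include is None or include in s:
                yield s


def ic_algorithm(
    data: pd.DataFrame,
    alpha: float = 0.05,
    prior: PriorKnowledge | None = None,
    node_types: Mapping[str, str] | None = None,
    max_cond: int | None = None,
) -> PDAG:
    """Inductive Causation: exhaustive separating-set search.

    Step 1 keeps an edge between every pair for which *no* subset of the
    remaining variables renders them independent at level ``alpha``.
    Step 2 directs unshielded triples as colliders when no separating set
    containing the middle vertex exists.  Step 3 propagates orientations
    (Meek rules) so that no new v-structures or directed cycles arise.
    Exponential in the number of variables; intended for <= ~15 nodes.
    """
    tester = CITester(data)
    nodes = tester.columns
    pdag = PDAG(nodes, node_types)
    limit = len(nodes) - 2 if max_cond is None else max_cond
    limit = min(limit, tester.n - 4)

    def separates(a, b, include=None):
        rest = [v for v in nodes if v not in (a, b)]
        for s in _subsets(rest, include=include):
            if len(s) > limit:
                break
            if tester.test(a, b, s).p > alpha:
                return s
        return None

    for a, b in itertools.combinations(nodes, 2):
        if prior is not None and prior.edge_excluded(a, b):
            continue
        if separates(a, b) is None:
            pdag.add_undirected(a, b)
    if prior is not None:
        for a, b in prior.whitelist:
            if not pdag.adjacent(a, b):
                pdag.add_undirected(a, b)

    _orient_v_structures(
        pdag, lambda a, b, c: separates(a, b, include=c) is None, prior
    )
    _apply_prior_orientations(pdag, prior)
    apply_meek_rules(pdag, prior)
    if not pdag.is_acyclic():  # should not happen; guard for finite samples
        raise RuntimeError("orientation produced a directed cycle")
    return pdag


# ---------------------------------------------------------------------------
# IAMB


def iamb_markov_blanket(
    data_or_tester, target: str, alpha: float = 0.05
) -> list:
    """Markov blanket of ``target`` by Incremental Association (IAMB).

    Grow phase: repeatedly admit the variable with the largest absolute
    Fisher Z association with the target given the current blanket,
    provided it is dependent at ``alpha`` (ties broken by name order).
    Shrink phase: discard any member that is independent of the target
    given the rest of the blanket.
    """
    tester = (
        data_or_tester
        if isinstance(data_or_tester, CITester)
        else CITester(data_or_tester)
    )
    others = [v for v in tester.columns if v != target]
    mb: list = []
    changed = True
    while changed:
        changed = False
        best, best_z, best_p = None, -np.inf, None
        for v in sorted(set(others) - set(mb)):
            if tester.n <= len(mb) + 3:
                break
            r = tester.test(target, v, mb)
            if abs(r.z) > best_z + 1e-12:
                best, best_z, best_p = v, abs(r.z), r.p
        if best is not None and best_p <= alpha:
            mb.append(best)
            changed = True
    # shrink
    removed = True
    while removed:
        removed = False
        for v in sorted(mb):
            rest = [u for u in mb if u != v]
            if tester.test(target, v, rest).p > alpha:
                mb.remove(v)
                removed = True
                break
    return sorted(mb)


def learn_structure_iamb(
    data: pd.DataFrame,
    alpha: float = 0.05,
    prior: PriorKnowledge | None = None,
    node_types: Mapping[str, str] | None = None,
) -> PDAG:
    """Blanket-first constraint-based learning (plain IAMB, AND symmetry).

    Markov blankets are estimated for every variable and symmetrised with
    the AND rule (both variables must contain each other).  Neighbours are
    then resolved by searching separating sets inside the union of the two
    blankets (restricting to the smaller blanket alone is cheaper but, when
    a finite-sample blanket is too small, degenerates to a single marginal
    test and leaves spurious edges the exhaustive IC search would remove);
    v-structures and Meek propagation follow as in :func:`ic_algorithm`,
    with separating-set searches again restricted to the blanket union.
    Prior constraints are enforced before propagation.
    """
    tester = CITester(data)
    nodes = tester.columns
    blankets = {v: set(iamb_markov_blanket(tester, v, alpha)) for v in nodes}
    for v in nodes:  # AND symmetry correction
        blankets[v] = {u for u in blankets[v] if v in blankets[u]}

    limit = tester.n - 4
    pdag = PDAG(nodes, node_types)

    def separates_within(a, b, pool, include=None):
        for s in _subsets(sorted(pool), include=include):
            if len(s) > limit:
                break
            if tester.test(a, b, s).p > alpha:
                return s
        return None

    for a, b in itertools.combinations(nodes, 2):
        if prior is not None and prior.edge_excluded(a, b):
            continue
        if b not in blankets[a]:
            continue
        pool = (blankets[a] | blankets[b]) - {a, b}
        if separates_within(a, b, pool) is None:
            pdag.add_undirected(a, b)
    if prior is not None:
        for a, b in prior.whitelist:
            if not pdag.adjacent(a, b):
                pdag.add_undirected(a, b)

    def collider_test(a, b, c):
        pool = (blankets[a] | blankets[b]) - {a, b}
        return separates_within(a, b, pool, include=c) is None

    _orient_v_structures(pdag, collider_test, prior)
    _apply_prior_orientations(pdag, prior)
    apply_meek_rules(pdag, prior)
    if not pdag.is_acyclic():
        raise RuntimeError("orientation produced a directed cycle")
    return pdag


# ---------------------------------------------------------------------------
# Trait adjustment (inputs to learning)


def adjust_phenotypes(trait_table: pd.DataFrame, traits: Sequence[str]) -> pd.DataFrame:
    """OLS residuals of each phenotype on sex + slaughter group + carcass
    weight; the variables actually entered into structure learning."""
    from .qtlscan import covariate_matrix, _residualize

    Z = covariate_matrix(trait_table)
    Y = trait_table.loc[:, list(traits)].to_numpy(dtype=float)
    R = _residualize(Z, Y)
    return pd.DataFrame(R, index=trait_table.index, columns=list(traits))


def adjust_expression(
    expression: pd.DataFrame, design: pd.DataFrame, probes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Expression corrected for dye and sex fixed effects and for the array
    random effect (its BLUP under the ML variance estimates); the grand
    mean is removed along with the fixed effects."""
    from .qtlscan import _ArrayTransform, covariate_matrix, fit_mixed_ml

    probes = list(probes) if probes is not None else list(expression.index)
    X = covariate_matrix(design, factors=("dye", "sex"), covariates=())
    tr = _ArrayTransform(design["array"])
    arrays = design["array"]
    Zmat = pd.get_dummies(arrays).to_numpy(dtype=float)
    out = {}
    for probe in probes:
        w = expression.loc[probe, design.index].to_numpy(dtype=float)
        fit = fit_mixed_ml(w, X, arrays, transform=tr)
        fixed = X @ fit.beta
        resid = w - fixed
        if fit.ratio > 0:
            # BLUP of array effects: u = ratio * Z' V^{-1} resid
            V = np.eye(len(w)) + fit.ratio * (Zmat @ Zmat.T)
            u = fit.ratio * (Zmat.T @ np.linalg.solve(V, resid))
            resid = resid - Zmat @ u
        out[probe] = resid
    return pd.DataFrame(out, index=design.index)
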