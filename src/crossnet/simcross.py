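"""Synthetic F2 line-cross studies with a known causal structure.

The generator emulates a two-breed F2 resource population (the default
mirrors a Duroc x Pietrain design: ~171 F2 animals, 124 microsatellite
markers on 19 linkage groups) in which a single pleiotropic QTL drives a
set of cis-regulated expression traits which in turn drive phenotypes,
all through a linear-Gaussian structural equation model.  Because the true
directed acyclic graph, its edge coefficients and the QTL location are
recorded, every downstream stage (scans, co-localization, structure
learning, effect estimation) can be tested for recovery of known truth.

F0/F1 generations are not simulated explicitly: under the assumption that
the founder breeds are fixed for alternative alleles, each F2 chromosome is
exactly the union of two independent F1 gametes, each a breed-origin mosaic
with crossovers placed by the Haldane map function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genomap import (
    EvaluationGrid,
    MarkerMap,
    STATE_OF_CODE,
    build_grid,
    haldane,
)

__all__ = [
    "TrueDAG",
    "NuisanceConfig",
    "SimConfig",
    "GroundTruth",
    "SimulatedGenotypes",
    "SimulatedStudy",
    "simulate_origin_genotypes",
    "simulate_traits",
    "simulate_study",
    "sample_sem",
    "default_config",
]


@dataclass(frozen=True)
class TrueDAG:
    """A directed acyclic graph with linear edge coefficients.

    ``node_types`` maps each node to ``genotype`` | ``expression`` |
    ``phenotype``; exactly one genotype node (the QTL) is expected.
    ``residual_sd`` gives the Gaussian noise standard deviation per node
    (ignored for the genotype node, whose value is the observed additive
    coefficient at the causal position).
    """

    node_types: Mapping[str, str]
    edges: Sequence[tuple[str, str, float]]
    residual_sd: Mapping[str, float]

    def __post_init__(self) -> None:
        nodes = set(self.node_types)
        for p, c, b in self.edges:
            if p not in nodes or c not in nodes:
                raise ValueError(f"edge ({p}, {c}) uses unknown node")
            if not np.isfinite(b):
                raise ValueError(f"edge ({p}, {c}) has non-finite coefficient")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("true_dag contains a directed cycle")
        for v, t in self.node_types.items():
            if t not in ("genotype", "expression", "phenotype"):
                raise ValueError(f"unknown node type {t!r} for {v!r}")
            if t != "genotype" and self.residual_sd.get(v, 1.0) <= 0:
                raise ValueError(f"residual_sd must be > 0 for {v!r}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_types)
        for p, c, b in self.edges:
            g.add_edge(p, c, coef=b)
        return g

    @property
    def genotype_node(self) -> str:
        geno = [v for v, t in self.node_types.items() if t == "genotype"]
        if len(geno) != 1:
            raise ValueError("exactly one genotype node required")
        return geno[0]

    def nodes_of_type(self, t: str) -> list[str]:
        return [v for v, tt in self.node_types.items() if tt == t]


@dataclass(frozen=True)
class NuisanceConfig:
    """Systematic effects layered on top of the causal signal.

    Phenotypes receive sex, slaughter-group and carcass-weight effects (the
    fixed-effect structure of the phenotype scan model); expression traits
    receive dye, sex and a random array effect (the microarray model).
    Carcass weight is by default a pure nuisance covariate, uncorrelated
    with anything causal.
    """

    sex_effect: float = 0.5
    n_groups: int = 4
    group_effect_sd: float = 0.3
    carcwt_slope: float = 0.05
    carcwt_mean: float = 85.0
    carcwt_sd: float = 7.0
    dye_effect: float = 0.3
    array_sd: float = 0.4
    expr_sex_effect: float = 0.2

    def __post_init__(self) -> None:
        if self.array_sd < 0:
            raise ValueError("array_sd must be >= 0")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated study."""

    n_f2: int
    map_spec: Sequence[tuple[float, int]]  # (length_cm, n_markers) per group
    qtl: tuple[str, float]  # (linkage group, cM)
    true_dag: TrueDAG
    nuisance: NuisanceConfig = field(default_factory=NuisanceConfig)
    n_null_probes: int = 0
    grid_k: int = 11
    single_channel: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 < 1:
            raise ValueError("n_f2 must be >= 1")
        for length, n in self.map_spec:
            if n < 1:
                raise ValueError("marker counts per group must be >= 1")
            if length <= 0:
                raise ValueError("group lengths must be > 0")

    def marker_map(self) -> MarkerMap:
        return MarkerMap.equally_spaced(self.map_spec)


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator knows and the analysis tries to recover."""

    dag: TrueDAG
    qtl_group: str
    qtl_cm: float
    qtl_grid_index: int
    cis_genes: tuple[str, ...]
    c_true: pd.Series  # additive coefficient at the causal locus per animal
    node_values: pd.DataFrame  # latent SEM values before nuisance effects


@dataclass(frozen=True)
class SimulatedGenotypes:
    """Observed breed-origin states at markers plus the hidden QTL state."""

    markers: pd.DataFrame  # animals x markers, DD/DP/PP strings
    qtl_state: pd.Series  # animals, DD/DP/PP at the causal position


@dataclass(frozen=True)
class SimulatedStudy:
    genotypes: SimulatedGenotypes
    trait_table: pd.DataFrame  # animal_id index; sex, group, carcwt, traits
    expression: pd.DataFrame  # probes x animals, log2 scale
    design: pd.DataFrame  # animal_id index; array, dye, sex
    marker_map: MarkerMap
    grid: EvaluationGrid
    truth: GroundTruth


def _simulate_gametes(rng, positions_cm: np.ndarray, n_gametes: int) -> np.ndarray:
    """Breed-origin alleles (1 = D, 0 = P) along one linkage group.

    Each gamete starts from a fair coin and switches origin between
    consecutive positions with the Haldane recombination fraction for the
    gap, i.e. crossovers without interference.
    """
    m = len(positions_cm)
    alleles = np.empty((n_gametes, m), dtype=np.int8)
    alleles[:, 0] = rng.random(n_gametes) < 0.5
    if m > 1:
        r = haldane(np.diff(positions_cm))
        switch = rng.random((n_gametes, m - 1)) < r[None, :]
        for j in range(1, m):
            alleles[:, j] = alleles[:, j - 1] ^ switch[:, j - 1]
    return alleles


def simulate_origin_genotypes(config: SimConfig, rng=None) -> SimulatedGenotypes:
    """Draw F2 breed-origin genotypes at all markers and at the QTL.

    Each animal's genome per linkage group is the sum of two independent
    F1-gamete mosaics; the genotype code is the number of D-origin alleles,
    reported as ``DD``/``DP``/``PP``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mmap = config.marker_map()
    qtl_group, qtl_cm = config.qtl
    if qtl_group not in mmap.groups:
        raise ValueError(f"QTL group {qtl_group!r} not in map")
    animals = pd.Index([f"A{i + 1:04d}" for i in range(config.n_f2)], name="animal_id")
    cols: dict[str, np.ndarray] = {}
    qtl_code = None
    for g in mmap.groups:
        sub = mmap.markers_of(g)
        pos = sub["cm"].to_numpy(dtype=float)
        names = list(sub["marker"])
        qtl_here = g == qtl_group
        if qtl_here:
            aug = np.sort(np.append(pos, qtl_cm))
            aug = np.unique(aug)
        else:
            aug = pos
        g1 = _simulate_gametes(rng, aug, config.n_f2)
        g2 = _simulate_gametes(rng, aug, config.n_f2)
        code = g1 + g2
        col_idx = np.searchsorted(aug, pos)
        for name, j in zip(names, col_idx):
            cols[name] = code[:, j]
        if qtl_here:
            qtl_code = code[:, int(np.searchsorted(aug, qtl_cm))]
    markers = pd.DataFrame(
        {m: [STATE_OF_CODE[c] for c in cols[m]] for m in mmap.table["marker"]},
        index=animals,
    )
    qtl_state = pd.Series(
        [STATE_OF_CODE[c] for c in qtl_code], index=animals, name="qtl_state"
    )
    return SimulatedGenotypes(markers=markers, qtl_state=qtl_state)


def _array_design(animals: pd.Index, rng, single_channel: bool) -> pd.DataFrame:
    """Assign animals to arrays; two-channel arrays pair animals with
    opposite dyes (an odd animal gets an array of its own)."""
    n = len(animals)
    order = rng.permutation(n)
    array = np.empty(n, dtype=object)
    dye = np.empty(n, dtype=object)
    if single_channel:
        for k, i in enumerate(order):
            array[i] = f"AR{k + 1:03d}"
            dye[i] = "cy3"
    else:
        for k in range(0, n, 2):
            aid = f"AR{k // 2 + 1:03d}"
            array[order[k]] = aid
            dye[order[k]] = "cy3"
            if k + 1 < n:
                array[order[k + 1]] = aid
                dye[order[k + 1]] = "cy5"
    return pd.DataFrame({"array": array, "dye": dye}, index=animals)


def simulate_traits(
    genotypes: SimulatedGenotypes, config: SimConfig, rng=None
) -> SimulatedStudy:
    """Propagate the causal signal through the true DAG and add nuisance.

    The genotype node takes the value ``c = 1{DD} - 1{PP}`` at the causal
    position.  Every other node is ``sum(coef * parent) + N(0, sd)`` in
    topological order.  Observed phenotypes add sex, slaughter-group and
    carcass-weight effects; observed expression adds dye, sex and a
    Gaussian per-array effect.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    dag = config.true_dag
    animals = genotypes.markers.index
    n = len(animals)
    code = genotypes.qtl_state.map({"DD": 2, "DP": 1, "PP": 0}).to_numpy()
    c_true = (code == 2).astype(float) - (code == 0).astype(float)

    g = dag.to_networkx()
    values: dict[str, np.ndarray] = {}
    qnode = dag.genotype_node
    for v in nx.topological_sort(g):
        if v == qnode:
            values[v] = c_true.copy()
            continue
        mean = np.zeros(n)
        for p in g.predecessors(v):
            mean = mean + g.edges[p, v]["coef"] * values[p]
        values[v] = mean + rng.normal(0.0, dag.residual_sd[v], size=n)
    node_values = pd.DataFrame(values, index=animals)

    nui = config.nuisance
    sex = pd.Series(np.where(rng.random(n) < 0.5, "F", "M"), index=animals)
    group = pd.Series(
        [f"G{k + 1}" for k in rng.integers(0, nui.n_groups, size=n)], index=animals
    )
    group_effects = {
        f"G{k + 1}": e
        for k, e in enumerate(rng.normal(0.0, nui.group_effect_sd, nui.n_groups))
    }
    carcwt = rng.normal(nui.carcwt_mean, nui.carcwt_sd, size=n)
    pheno_nuisance = (
        nui.sex_effect * (sex == "M").to_numpy(dtype=float)
        + group.map(group_effects).to_numpy()
        + nui.carcwt_slope * (carcwt - nui.carcwt_mean)
    )
    trait_table = pd.DataFrame(
        {"sex": sex, "group": group, "carcwt": carcwt}, index=animals
    )
    for ph in dag.nodes_of_type("phenotype"):
        trait_table[ph] = node_values[ph] + pheno_nuisance

    design = _array_design(animals, rng, config.single_channel)
    design["sex"] = sex
    arrays = design["array"].unique()
    array_effects = dict(zip(arrays, rng.normal(0.0, nui.array_sd, len(arrays))))
    expr_nuisance = (
        nui.dye_effect * (design["dye"] == "cy5").to_numpy(dtype=float)
        + nui.expr_sex_effect * (sex == "M").to_numpy(dtype=float)
        + design["array"].map(array_effects).to_numpy()
    )
    expr_rows = {}
    for gene in dag.nodes_of_type("expression"):
        expr_rows[gene] = node_values[gene].to_numpy() + expr_nuisance
    for k in range(config.n_null_probes):
        expr_rows[f"NULL{k + 1:03d}"] = rng.normal(0.0, 1.0, n) + expr_nuisance
    expression = pd.DataFrame(expr_rows, index=animals).T
    expression.index.name = "probe"

    mmap = config.marker_map()
    grid = build_grid(mmap, k=config.grid_k)
    truth = GroundTruth(
        dag=dag,
        qtl_group=config.qtl[0],
        qtl_cm=config.qtl[1],
        qtl_grid_index=grid.nearest_index(config.qtl[0], config.qtl[1]),
        cis_genes=tuple(
            c
            for p, c, _b in dag.edges
            if p == qnode and dag.node_types[c] == "expression"
        ),
        c_true=pd.Series(c_true, index=animals, name="c_true"),
        node_values=node_values,
    )
    return SimulatedStudy(
        genotypes=genotypes,
        trait_table=trait_table,
        expression=expression,
        design=design,
        marker_map=mmap,
        grid=grid,
        truth=truth,
    )


def sample_sem(dag: TrueDAG, n: int, rng=None) -> pd.DataFrame:
    """Draw ``n`` observations of the bare SEM node values (no nuisance).

    The genotype node is drawn from the F2 additive-coefficient
    distribution ``P(c = 1) = P(c = -1) = 1/4, P(c = 0) = 1/2`` (Mendelian
    segregation at a fully informative locus); every other node follows
    its linear-Gaussian local distribution.
    """
    rng = np.random.default_rng(rng)
    g = dag.to_networkx()
    geno = dag.nodes_of_type("genotype")
    values: dict[str, np.ndarray] = {}
    for v in nx.topological_sort(g):
        if v in geno:
            code = rng.integers(0, 2, size=n) + rng.integers(0, 2, size=n)
            values[v] = (code - 1).astype(float)
            continue
        mean = np.zeros(n)
        for p in g.predecessors(v):
            mean = mean + g.edges[p, v]["coef"] * values[p]
        values[v] = mean + rng.normal(0.0, dag.residual_sd[v], size=n)
    return pd.DataFrame(values)


def simulate_study(config: SimConfig, seed: int | None = None) -> SimulatedStudy:
    """Convenience wrapper: genotypes then traits from one seeded stream.

    Sub-streams for the genotype and trait stages are spawned
    deterministically from the master seed, so the whole study is
    bit-reproducible.
    """
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    ss_geno, ss_trait = master.spawn(2)
    geno = simulate_origin_genotypes(config, np.random.default_rng(ss_geno))
    return simulate_traits(geno, config, np.random.default_rng(ss_trait))


# ---------------------------------------------------------------------------
# Default study: a pleiotropic QTL on linkage group 6 feeding seven
# cis-regulated genes which mediate its effect on two fat-deposition
# phenotypes (BF10, FAT) and, negatively, on loin muscle weight (LOIN).

_DEFAULT_MAP: tuple[tuple[float, int], ...] = (
    (120, 8), (110, 7), (100, 7), (105, 7), (95, 6), (140, 9),
    (120, 8), (100, 7), (95, 6), (85, 6), (80, 5), (90, 6),
    (95, 7), (100, 7), (85, 6), (75, 5), (60, 4), (55, 4), (50, 9),
)  # 124 markers on 19 linkage groups

_DEFAULT_EDGES: tuple[tuple[str, str, float], ...] = (
    ("QTL", "G1", 1.0),
    ("QTL", "G2", 0.9),
    ("QTL", "G3", -0.9),
    ("QTL", "G4", 0.8),
    ("QTL", "G5", -0.8),
    ("QTL", "G6", 0.7),
    ("QTL", "G7", -0.7),
    ("G1", "G2", 0.5),
    ("QTL", "FAT", 0.5),
    ("G1", "BF10", 0.8),
    ("G2", "FAT", 0.7),
    ("G5", "LOIN", 0.6),
    ("BF10", "LOIN", -0.5),
    ("FAT", "LOIN", -0.4),
)


def default_true_dag() -> TrueDAG:
    nodes = {"QTL": "genotype"}
    nodes.update({f"G{i}": "expression" for i in range(1, 8)})
    nodes.update({"BF10": "phenotype", "FAT": "phenotype", "LOIN": "phenotype"})
    sd = {v: 1.0 for v in nodes if v != "QTL"}
    return TrueDAG(node_types=nodes, edges=_DEFAULT_EDGES, residual_sd=sd)


def default_config(
    n_f2: int = 171, n_null_probes: int = 33, seed: int = 0, **overrides
) -> SimConfig:
    """The default study: 171 F2 animals, 124 markers on 19 groups, one
    pleiotropic QTL at 70 cM of LG6, seven cis genes, three phenotypes."""
    kwargs = dict(
        n_f2=n_f2,
        map_spec=_DEFAULT_MAP,
        qtl=("LG6", 70.0),
        true_dag=default_true_dag(),
        n_null_probes=n_null_probes,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
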