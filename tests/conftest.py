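import numpy as np
import pytest

from crossnet import genomap
from crossnet.simcross import TrueDAG, default_config, simulate_study


def make_random_dag(rng, n_nodes=8, p_edge=0.2, with_genotype=True):
    """Random sparse linear-Gaussian DAG with |coef| in [0.5, 1]."""
    names = [f"V{i}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                coef = float(rng.choice([-1, 1]) * rng.uniform(0.5, 1.0))
                edges.append((names[i], names[j], coef))
    types = {v: "phenotype" for v in names}
    if with_genotype:
        types[names[0]] = "genotype"
    return TrueDAG(types, edges, {v: 1.0 for v in names})


def true_v_structures(dag: TrueDAG) -> set:
    import itertools

    g = dag.to_networkx()
    out = set()
    for c in g.nodes:
        for a, b in itertools.combinations(sorted(g.predecessors(c)), 2):
            if not (g.has_edge(a, b) or g.has_edge(b, a)):
                out.add((a, c, b))
    return out


SMALL_MAP = ((100, 6), (120, 7), (80, 5), (100, 6), (90, 5), (140, 9))


@pytest.fixture(scope="session")
def small_study():
    """Reduced-map default study: 6 linkage groups, QTL on LG6 at 70 cM,
    seven cis genes, three phenotypes, no null probes."""
    cfg = default_config(
        seed=11, n_null_probes=0, map_spec=SMALL_MAP, qtl=("LG6", 70.0)
    )
    return simulate_study(cfg, seed=11)


@pytest.fixture(scope="session")
def small_probs(small_study):
    return genomap.origin_probabilities(
        small_study.genotypes.markers, small_study.marker_map, small_study.grid
    )
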