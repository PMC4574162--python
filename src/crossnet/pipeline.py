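"""End-to-end orchestration and file formats.

All tables are tab-separated with a mandatory header row; lines starting
with ``#`` are comments.  Networks travel as SIF (``node<TAB>relation<TAB>
node`` with relation ``->`` or ``--``), as GraphML with coefficient
attributes, and as DOT for rendering.  ``run_pipeline`` executes the full
multistep flow — simulate, phenotype scan, expression scan,
co-localization, structure learning, ML effect estimation, path
decomposition, jackknife — and writes a versioned machine-readable
summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import causalnet, coloc, effects, genomap, qtlscan, simcross

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

__all__ = [
    "read_table",
    "write_table",
    "read_marker_map",
    "write_marker_map",
    "read_trait_table",
    "write_trait_table",
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "read_genotypes",
    "write_genotypes",
    "write_origin_probs",
    "read_prior",
    "write_prior",
    "read_sif",
    "write_sif",
    "write_graphml",
    "write_dot",
    "PipelineConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# TSV primitives


def read_table(path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    except Exception as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    return df


def write_table(df: pd.DataFrame, path, index=False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_marker_map(path) -> genomap.MarkerMap:
    df = read_table(path)
    _require_columns(df, ["group", "marker", "cm"], path)
    return genomap.MarkerMap(df)


def write_marker_map(mmap: genomap.MarkerMap, path) -> None:
    write_table(mmap.table, path)


def read_trait_table(path) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, ["animal_id", "sex", "group", "carcwt"], path)
    df = df.set_index("animal_id")
    for col in ("sex", "group", "carcwt"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(
                f"{path}: missing {col!r} for animal {bad[0]!r}"
            )
    return df


def write_trait_table(traits: pd.DataFrame, path) -> None:
    write_table(traits.reset_index(names="animal_id"), path)


def read_expression(path) -> pd.DataFrame:
    df = read_table(path, index_col=0)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite expression values")
    df.columns.name = "animal_id"  # probes x animals
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    out = expr.copy()
    out.index.name = out.index.name or "probe"
    write_table(out.reset_index(), path)


def read_design(path) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, ["animal_id", "array", "dye"], path)
    return df.set_index("animal_id")


def write_design(design: pd.DataFrame, path) -> None:
    write_table(design.reset_index(names="animal_id"), path)


def read_genotypes(path) -> pd.DataFrame:
    return read_table(path, index_col=0)


def write_genotypes(genos: pd.DataFrame, path) -> None:
    out = genos.copy()
    out.index.name = out.index.name or "animal_id"
    write_table(out.reset_index(), path)


def write_origin_probs(probs: genomap.OriginProb, path) -> None:
    write_table(probs.to_frame(), path)


def write_grid(grid: genomap.EvaluationGrid, path) -> None:
    write_table(grid.table, path)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# Prior YAML, SIF, GraphML, DOT


def read_prior(path) -> causalnet.PriorKnowledge:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    wl = tuple(tuple(e) for e in raw.get("whitelist", ()))
    bl = tuple(tuple(e) for e in raw.get("blacklist", ()))
    return causalnet.PriorKnowledge(
        whitelist=wl,
        blacklist=bl,
        genotype_exogenous=bool(raw.get("genotype_exogenous", True)),
    )


def write_prior(prior: causalnet.PriorKnowledge, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "whitelist": [list(e) for e in prior.whitelist],
                "blacklist": [list(e) for e in prior.blacklist],
                "genotype_exogenous": prior.genotype_exogenous,
            },
            fh,
        )


def read_sif(path, node_types: Mapping[str, str] | None = None) -> causalnet.PDAG:
    directed, undirected, nodes = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                nodes.append(parts[0])
                continue
            if len(parts) != 3 or parts[1] not in ("->", "--"):
                raise ValueError(f"{path}:{lineno}: malformed SIF line {line!r}")
            a, rel, b = parts
            nodes += [a, b]
            (directed if rel == "->" else undirected).append((a, b))
    pdag = causalnet.PDAG(list(dict.fromkeys(nodes)), node_types)
    for a, b in directed:
        pdag.add_directed(a, b)
    for a, b in undirected:
        pdag.add_undirected(a, b)
    return pdag


def write_sif(pdag: causalnet.PDAG, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    connected = set()
    with open(path, "w") as fh:
        for a, b in pdag.directed_edges:
            fh.write(f"{a}\t->\t{b}\n")
            connected |= {a, b}
        for a, b in pdag.undirected_edges:
            fh.write(f"{a}\t--\t{b}\n")
            connected |= {a, b}
        for v in pdag.nodes:
            if v not in connected:
                fh.write(f"{v}\n")


def write_graphml(graph, path) -> None:
    """GraphML export; PDAGs encode undirected edges with ``directed='no'``
    edge attributes on a directed graph."""
    if isinstance(graph, causalnet.PDAG):
        g = nx.DiGraph()
        g.add_nodes_from(graph.nodes)
        for v in graph.nodes:
            g.nodes[v]["type"] = graph.node_types.get(v, "")
        for a, b in graph.directed_edges:
            g.add_edge(a, b, arrow="yes")
        for a, b in graph.undirected_edges:
            g.add_edge(a, b, arrow="no")
    else:
        g = graph
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)


def write_dot(fitted: effects.LinearSEMResults | causalnet.PDAG, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lines = ["digraph crossnet {"]
    if isinstance(fitted, causalnet.PDAG):
        for a, b in fitted.directed_edges:
            lines.append(f'  "{a}" -> "{b}";')
        for a, b in fitted.undirected_edges:
            lines.append(f'  "{a}" -> "{b}" [dir=none];')
    else:
        for _, r in fitted.params.iterrows():
            lines.append(
                f'  "{r["parent"]}" -> "{r["child"]}" [label="{r["coef"]:.3f}"];'
            )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Settings for one end-to-end run.

    Either ``simulate`` holds a :class:`~crossnet.simcross.SimConfig` (the
    study is generated) or the four input paths point at existing tables.
    """

    seed: int
    out_dir: str
    simulate: simcross.SimConfig | None = None
    marker_map_path: str | None = None
    trait_path: str | None = None
    expression_path: str | None = None
    design_path: str | None = None
    genotype_path: str | None = None
    grid_k: int = 11
    n_perm: int = 1000
    level: float = 0.05
    fdr: float = 0.20
    window_cm: float = 20.0
    min_pqtl: int = 1
    min_eqtl: int = 1
    algorithm: str = "iamb"
    alpha: float = 0.05
    prior: causalnet.PriorKnowledge = field(
        default_factory=causalnet.PriorKnowledge
    )
    jackknife: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = None
        if "simulate" in raw:
            s = dict(raw["simulate"])
            if "true_dag" in s:
                td = s["true_dag"]
                s["true_dag"] = simcross.TrueDAG(
                    node_types=td["node_types"],
                    edges=[tuple(e) for e in td["edges"]],
                    residual_sd=td["residual_sd"],
                )
            else:
                s["true_dag"] = simcross.default_true_dag()
            if "map_spec" in s:
                s["map_spec"] = [tuple(m) for m in s["map_spec"]]
            if "nuisance" in s:
                s["nuisance"] = simcross.NuisanceConfig(**s["nuisance"])
            if "qtl" in s:
                s["qtl"] = tuple(s["qtl"])
            sim = simcross.SimConfig(**s)
        prior = causalnet.PriorKnowledge(
            whitelist=tuple(tuple(e) for e in raw.get("prior", {}).get("whitelist", ())),
            blacklist=tuple(tuple(e) for e in raw.get("prior", {}).get("blacklist", ())),
            genotype_exogenous=raw.get("prior", {}).get("genotype_exogenous", True),
        )
        keys = (
            "seed out_dir marker_map_path trait_path expression_path design_path "
            "genotype_path grid_k n_perm level fdr window_cm min_pqtl min_eqtl "
            "algorithm alpha jackknife"
        ).split()
        kwargs = {k: raw[k] for k in keys if k in raw}
        return cls(simulate=sim, prior=prior, **kwargs)


def _stage_log(run_log: list, stage: str, **params) -> None:
    entry = {"stage": stage, **params}
    run_log.append(entry)
    logger.info("stage %s: %s", stage, params)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the multistep flow and write stage outputs + summary JSON.

    Stage order: simulate (optional) -> phenotype scan -> expression scan
    -> co-localization -> structure learning -> ML fit -> path
    decomposition -> jackknife.  Any stage error halts the run with the
    stage name in the exception; outputs of completed stages remain on
    disk.  Fully deterministic given the config seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: list = []
    master = np.random.SeedSequence(config.seed)
    ss_sim, ss_scan = master.spawn(2)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "seed": config.seed}

    try:
        # --- inputs -------------------------------------------------------
        if config.simulate is not None:
            stage = "simulate"
            study = simcross.simulate_study(
                config.simulate, seed=int(ss_sim.generate_state(1)[0] % (2**31))
            )
            mmap, grid = study.marker_map, study.grid
            traits, expr, design = study.trait_table, study.expression, study.design
            genos = study.genotypes.markers
            write_marker_map(mmap, out / "marker_map.tsv")
            write_trait_table(traits, out / "traits.tsv")
            write_expression(expr, out / "expression.tsv")
            write_design(design, out / "design.tsv")
            write_genotypes(genos, out / "genotypes.tsv")
            _write_truth(study.truth, out / "truth")
            _stage_log(run_log, stage, n_f2=config.simulate.n_f2)
        else:
            stage = "load"
            mmap = read_marker_map(config.marker_map_path)
            traits = read_trait_table(config.trait_path)
            expr = read_expression(config.expression_path)
            design = read_design(config.design_path)
            genos = read_genotypes(config.genotype_path)
            _check_ids(traits, expr, design, genos)
            grid = genomap.build_grid(mmap, k=config.grid_k)
            study = None
            _stage_log(run_log, stage, n=len(traits))

        stage = "origin-probabilities"
        probs = genomap.origin_probabilities(genos, mmap, grid)
        write_origin_probs(probs, out / "origin_probs.tsv")
        write_grid(grid, out / "grid.tsv")
        _stage_log(run_log, stage, n_positions=grid.n_positions)

        stage = "scan-pheno"
        scan_seed = int(ss_scan.generate_state(2)[0] % (2**31))
        pres = qtlscan.PhenotypeScan(traits, probs).fit(
            n_perm=config.n_perm, level=config.level, seed=scan_seed
        )
        for trait, table in pres.tables.items():
            t = table.copy()
            t["threshold"] = pres.thresholds[trait]
            write_table(t, out / f"scan_pheno_{trait}.tsv")
        write_table(pres.summary(), out / "scan_pheno_summary.tsv")
        _stage_log(
            run_log, stage, n_perm=config.n_perm, level=config.level, seed=scan_seed
        )

        stage = "scan-expr"
        eres = qtlscan.ExpressionScan(expr, design, probs).fit(fdr_level=config.fdr)
        write_table(eres.best, out / "scan_expr_best.tsv")
        write_table(eres.significant(), out / "scan_expr_significant.tsv")
        _stage_log(run_log, stage, fdr=config.fdr, n_probes=len(expr))

        stage = "coloc"
        regions = coloc.find_colocalized_regions(
            pres,
            eres,
            grid=grid,
            window_cm=config.window_cm,
            min_pqtl=config.min_pqtl,
            min_eqtl=config.min_eqtl,
        )
        write_table(
            pd.DataFrame([dataclasses.asdict(r) for r in regions]),
            out / "regions.tsv",
        )
        summary["regions"] = [dataclasses.asdict(r) for r in regions]
        _stage_log(run_log, stage, n_regions=len(regions))

        if not regions:
            summary["status"] = "no region"
            logger.info("no co-localized region; stopping after coloc")
        else:
            region = regions[0]
            stage = "learn"
            data, node_types = coloc.region_dataset(
                region, traits, expr, design, probs
            )
            write_table(
                data.reset_index(names="animal_id"), out / "region_data.tsv"
            )
            learn = (
                causalnet.learn_structure_iamb
                if config.algorithm == "iamb"
                else causalnet.ic_algorithm
            )
            pdag = learn(
                data, alpha=config.alpha, prior=config.prior, node_types=node_types
            )
            write_sif(pdag, out / "network.sif")
            write_graphml(pdag, out / "network.graphml")
            _stage_log(
                run_log,
                stage,
                algorithm=config.algorithm,
                alpha=config.alpha,
                n_undirected=len(pdag.undirected_edges),
            )

            stage = "fit"
            try:
                dag = effects.extend_to_dag(pdag, config.prior)
            except ValueError as exc:
                logger.warning("strict extension failed (%s); retrying best-effort", exc)
                dag = effects.extend_to_dag(pdag, config.prior, best_effort=True)
                summary["extension"] = "best_effort"
            fitted = effects.fit_ml(dag, data)
            write_table(fitted.params, out / "edges.tsv")
            write_table(fitted.node_stats, out / "nodes.tsv")
            write_dot(fitted, out / "network.dot")
            summary["edges"] = fitted.params.to_dict(orient="records")
            summary["nodes"] = fitted.node_stats.to_dict(orient="records")
            _stage_log(run_log, stage, n_edges=len(fitted.params))

            stage = "paths"
            anchor = region.anchor_label
            path_rows = []
            for ph in region.phenotypes:
                dec = fitted.total_effect(anchor, ph)
                for p, e in zip(dec.paths, dec.path_effects):
                    path_rows.append(
                        {"sink": ph, "path": " -> ".join(p), "effect": e}
                    )
                path_rows.append(
                    {"sink": ph, "path": "(total)", "effect": dec.total}
                )
            write_table(pd.DataFrame(path_rows), out / "paths.tsv")
            summary["total_effects"] = {
                ph: effects.total_effect(fitted, anchor, ph).total
                for ph in region.phenotypes
            }
            _stage_log(run_log, stage, anchor=anchor)

            if config.jackknife:
                stage = "stability"
                learner = lambda d: learn(  # noqa: E731
                    d,
                    alpha=config.alpha,
                    prior=config.prior,
                    node_types=node_types,
                )
                rep = effects.jackknife_stability(data, learner, reference=pdag)
                write_table(rep.table, out / "stability.tsv")
                summary["stability"] = rep.table.to_dict(orient="records")
                summary["jackknife_failed"] = rep.n_failed
                _stage_log(run_log, stage, n_resamples=rep.n_resamples)
            summary["status"] = "ok"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["stages"] = run_log
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (tuple, set)):
        return list(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_truth(truth: simcross.GroundTruth, stem: Path) -> None:
    stem.parent.mkdir(parents=True, exist_ok=True)
    pdag = causalnet.PDAG(list(truth.dag.node_types), truth.dag.node_types)
    for p, c, _b in truth.dag.edges:
        pdag.add_directed(p, c)
    write_sif(pdag, stem.with_suffix(".sif"))
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(
            {
                "edges": [list(e) for e in truth.dag.edges],
                "qtl_group": truth.qtl_group,
                "qtl_cm": truth.qtl_cm,
                "qtl_grid_index": truth.qtl_grid_index,
                "cis_genes": list(truth.cis_genes),
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def _check_ids(traits, expr, design, genos) -> None:
    base = set(traits.index)
    for name, ids in (
        ("design", set(design.index)),
        ("genotypes", set(genos.index)),
        ("expression", set(expr.columns)),
    ):
        if set(ids) != base:
            diff = sorted(base.symmetric_difference(ids))[:5]
            raise ValueError(
                f"animal identifiers of {name} do not match trait table: {diff}"
            )
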