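"""Co-localization of significant pQTL and eQTL.

Regions of the genome where one or more genome-wise significant phenotype
QTL co-map with several significant expression QTL nominate the variable
sets (anchor genotype + phenotypes + expression traits) on which causal
network learning is attempted.  Clustering is greedy and peak-first:
the most significant unassigned pQTL peak seeds a region, and every
significant pQTL peak or eQTL best position on the same linkage group
within ``window_cm`` of the seed joins it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomap import EvaluationGrid

__all__ = ["ColocRegion", "find_colocalized_regions", "region_dataset"]


@dataclass(frozen=True)
class ColocRegion:
    """A pQTL/eQTL co-mapping region on one linkage group."""

    group: str
    cm_min: float
    cm_max: float
    anchor_index: int  # grid index of the most significant pQTL position
    anchor_cm: float
    anchor_label: str  # e.g. "@LG6.139"
    phenotypes: tuple
    probes: tuple

    @property
    def interval(self) -> tuple[float, float]:
        return (self.cm_min, self.cm_max)


def find_colocalized_regions(
    pqtl_results,
    eqtl_results,
    grid: EvaluationGrid | None = None,
    window_cm: float = 20.0,
    min_pqtl: int = 1,
    min_eqtl: int = 1,
) -> list:
    """Cluster significant pQTL peaks and attach nearby significant eQTL.

    Parameters
    ----------
    pqtl_results : :class:`~crossnet.qtlscan.PhenotypeScanResults` (scan
        tables + per-trait genome-wise thresholds).
    eqtl_results : :class:`~crossnet.qtlscan.ExpressionScanResults` (per
        probe best positions + q-values).
    window_cm : half-width around the seed peak within which peaks and
        eQTL on the same linkage group are absorbed.

    Regions failing ``min_pqtl`` / ``min_eqtl`` member counts are dropped;
    regions on one linkage group are disjoint by construction and every
    significant pQTL peak belongs to at most one region.
    """
    # significant pQTL peaks: per trait per linkage group, the strongest
    # position exceeding the trait's genome-wise threshold
    peaks = []
    for trait, table in sorted(pqtl_results.tables.items()):
        thr = pqtl_results.thresholds[trait]
        sig = table[table["F"] >= thr]
        if len(sig) == 0:
            continue
        for g, sub in sig.groupby("group", sort=False):
            row = sub.loc[sub["F"].idxmax()]
            peaks.append(
                {
                    "trait": trait,
                    "group": g,
                    "cm": float(row["cm"]),
                    "index": int(row["index"]),
                    "F": float(row["F"]),
                    "p": float(row["p"]),
                }
            )
    peaks = pd.DataFrame(peaks, columns=["trait", "group", "cm", "index", "F", "p"])

    sig_eqtl = eqtl_results.significant() if eqtl_results is not None else pd.DataFrame(
        columns=["probe", "group", "cm", "index", "q"]
    )

    if grid is None:
        grid = getattr(eqtl_results, "grid", None)

    regions = []
    unassigned = peaks.sort_values(["p", "trait"]).reset_index(drop=True)
    taken = np.zeros(len(unassigned), dtype=bool)
    for i in range(len(unassigned)):
        if taken[i]:
            continue
        seed = unassigned.iloc[i]
        same = (
            (unassigned["group"] == seed["group"])
            & (np.abs(unassigned["cm"] - seed["cm"]) <= window_cm)
            & ~taken
        )
        members = unassigned[same]
        taken |= same.to_numpy()
        probes = sig_eqtl[
            (sig_eqtl["group"] == seed["group"])
            & (np.abs(sig_eqtl["cm"] - seed["cm"]) <= window_cm)
        ]
        if members["trait"].nunique() < min_pqtl or probes["probe"].nunique() < min_eqtl:
            continue
        cms = list(members["cm"]) + list(probes["cm"])
        anchor_idx = int(seed["index"])
        label = (
            _label(grid, anchor_idx)
            if grid is not None
            else f"@{seed['group']}.{anchor_idx}"
        )
        regions.append(
            ColocRegion(
                group=seed["group"],
                cm_min=float(min(cms)),
                cm_max=float(max(cms)),
                anchor_index=anchor_idx,
                anchor_cm=float(seed["cm"]),
                anchor_label=label,
                phenotypes=tuple(sorted(members["trait"].unique())),
                probes=tuple(sorted(probes["probe"].unique())),
            )
        )
    return regions


def _label(grid: EvaluationGrid, index: int) -> str:
    return grid.position_label(index)


def region_dataset(
    region: ColocRegion,
    trait_table: pd.DataFrame,
    expression: pd.DataFrame,
    design: pd.DataFrame,
    probs,
) -> tuple[pd.DataFrame, dict]:
    """Bundle the variables entering structure learning for one region.

    Returns ``(data, node_types)``: the anchor's additive coefficient
    ``c`` plus the region's phenotypes (adjusted for sex, group and
    carcass weight) and probes (adjusted for dye, sex and array effects),
    one column per variable, indexed by animal.
    """
    from .causalnet import adjust_expression, adjust_phenotypes

    trait_table = trait_table.loc[probs.animals]
    design = design.loc[probs.animals]
    expression = expression.loc[:, probs.animals]
    cols = {region.anchor_label: probs.c[:, region.anchor_index]}
    node_types = {region.anchor_label: "genotype"}
    adj_ph = adjust_phenotypes(trait_table, region.phenotypes)
    for ph in region.phenotypes:
        cols[ph] = adj_ph[ph].to_numpy()
        node_types[ph] = "phenotype"
    if region.probes:
        adj_ex = adjust_expression(expression, design, region.probes)
        for pr in region.probes:
            cols[pr] = adj_ex[pr].to_numpy()
            node_types[pr] = "expression"
    data = pd.DataFrame(cols, index=trait_table.index)
    return data, node_types
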