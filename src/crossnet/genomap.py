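"""Evaluation grids and breed-of-origin probabilities for an F2 line cross.

A line cross between two divergent founder breeds (here called ``D`` for
Duroc-origin and ``P`` for Pietrain-origin alleles) is scanned for QTL at
marker positions and at a number of equidistant pseudo-positions inside each
inter-marker interval.  At every scan position each F2 animal is summarised
by the probabilities of carrying two D alleles (``P11``), one of each
(``P12``) or two P alleles (``P22``), and by the additive coefficient
``c = P11 - P22`` used as the regressor for an allele-substitution effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "EvaluationGrid",
    "OriginProb",
    "haldane",
    "build_grid",
    "origin_probabilities",
    "additive_coefficient",
]

# Integer genotype codes = number of D-origin alleles.
CODE_PP, CODE_DP, CODE_DD = 0, 1, 2
CODE_OF_STATE = {"PP": CODE_PP, "DP": CODE_DP, "PD": CODE_DP, "DD": CODE_DD}
STATE_OF_CODE = {CODE_PP: "PP", CODE_DP: "DP", CODE_DD: "DD"}


def haldane(d_cm):
    """Recombination fraction for a map distance ``d_cm`` (centimorgan).

    Haldane's map function assumes crossovers occur as a Poisson process
    with no interference: ``r = 0.5 * (1 - exp(-2 d / 100))``.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker positions on a set of linkage groups.

    Parameters
    ----------
    table : DataFrame with columns ``group``, ``marker``, ``cm``; markers
        must be strictly increasing in ``cm`` within each group.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "marker", "cm"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        if len(self.table) == 0:
            raise ValueError("marker map is empty")
        if self.table["marker"].duplicated().any():
            dup = self.table.loc[self.table["marker"].duplicated(), "marker"]
            raise ValueError(f"duplicate marker names: {sorted(set(dup))}")
        for g, sub in self.table.groupby("group", sort=False):
            cm = sub["cm"].to_numpy(dtype=float)
            if len(cm) >= 2 and not np.all(np.diff(cm) > 0):
                raise ValueError(
                    f"marker positions not strictly increasing in group {g!r}"
                )

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.table["group"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def markers_of(self, group) -> pd.DataFrame:
        return self.table[self.table["group"] == group].reset_index(drop=True)

    @classmethod
    def equally_spaced(
        cls, spec: Sequence[tuple[float, int]], group_names: Sequence | None = None
    ) -> "MarkerMap":
        """Build a map from ``(length_cm, n_markers)`` pairs, one per group.

        Markers are placed at equal spacing from 0 to ``length_cm`` (a single
        marker sits at the midpoint).
        """
        rows = []
        for i, (length, n) in enumerate(spec):
            if n < 1:
                raise ValueError("each group needs at least one marker")
            g = group_names[i] if group_names is not None else f"LG{i + 1}"
            pos = [length / 2.0] if n == 1 else list(np.linspace(0.0, length, n))
            for j, cm in enumerate(pos):
                rows.append({"group": g, "marker": f"{g}M{j + 1}", "cm": float(cm)})
        return cls(pd.DataFrame(rows))


@dataclass(frozen=True)
class EvaluationGrid:
    """Scan positions: every marker plus ``k`` pseudo-positions per interval.

    ``table`` columns: ``index`` (0-based over the whole genome), ``group``,
    ``cm``, ``kind`` (``marker`` | ``pseudo``), ``marker`` (name, or the
    flanking interval label for pseudo positions).
    """

    table: pd.DataFrame
    k: int

    @property
    def n_positions(self) -> int:
        return len(self.table)

    def position_label(self, index: int) -> str:
        """Label like ``@LG6.139``: linkage group plus 1-based grid index
        counted within the group (mirrors the field's ``@Chr6.139`` style)."""
        row = self.table.iloc[index]
        within = (self.table["group"] == row["group"]) & (
            self.table["index"] <= row["index"]
        )
        return f"@{row['group']}.{int(within.sum())}"

    def nearest_index(self, group, cm: float) -> int:
        sub = self.table[self.table["group"] == group]
        if len(sub) == 0:
            raise KeyError(f"unknown linkage group {group!r}")
        i = (sub["cm"] - cm).abs().idxmin()
        return int(sub.loc[i, "index"])


def build_grid(marker_map: MarkerMap, k: int = 11) -> EvaluationGrid:
    """Insert ``k`` equidistant pseudo-positions into every marker interval.

    The resulting position count is ``n_markers + k * (n_markers - n_groups)``;
    pseudo-positions sit at interval fractions ``j/(k+1)`` for ``j = 1..k``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rows = []
    idx = 0
    for g in marker_map.groups:
        sub = marker_map.markers_of(g)
        for i in range(len(sub)):
            rows.append(
                {
                    "index": idx,
                    "group": g,
                    "cm": float(sub.loc[i, "cm"]),
                    "kind": "marker",
                    "marker": sub.loc[i, "marker"],
                }
            )
            idx += 1
            if i + 1 < len(sub):
                left, right = float(sub.loc[i, "cm"]), float(sub.loc[i + 1, "cm"])
                label = f"{sub.loc[i, 'marker']}|{sub.loc[i + 1, 'marker']}"
                for j in range(1, k + 1):
                    rows.append(
                        {
                            "index": idx,
                            "group": g,
                            "cm": left + (right - left) * j / (k + 1),
                            "kind": "pseudo",
                            "marker": label,
                        }
                    )
                    idx += 1
    return EvaluationGrid(pd.DataFrame(rows), k=k)


@dataclass(frozen=True)
class OriginProb:
    """Breed-of-origin probabilities per animal x grid position.

    ``p11``, ``p12``, ``p22`` are ``(n_animals, n_positions)`` arrays; rows
    of ``(p11, p12, p22)`` sum to one at every position.
    """

    animals: pd.Index
    grid: EvaluationGrid
    p11: np.ndarray
    p12: np.ndarray
    p22: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.animals), self.grid.n_positions)
        for name in ("p11", "p12", "p22"):
            a = getattr(self, name)
            if a.shape != shape:
                raise ValueError(f"{name} has shape {a.shape}, expected {shape}")
        s = self.p11 + self.p12 + self.p22
        ok = np.isnan(s) | (np.abs(s - 1.0) < 1e-9)
        if not ok.all():
            raise ValueError("origin probabilities do not sum to 1")

    @property
    def c(self) -> np.ndarray:
        """Additive coefficient ``P11 - P22`` per animal x position.

        The printed formula is the conditional expectation of the number of
        D alleles *minus one*, so ``c`` ranges over ``[-1, 1]``.
        """
        return additive_coefficient(self)

    def to_frame(self) -> pd.DataFrame:
        n, p = self.p11.shape
        return pd.DataFrame(
            {
                "animal_id": np.repeat(np.asarray(self.animals), p),
                "position_index": np.tile(np.arange(p), n),
                "P11": self.p11.ravel(),
                "P12": self.p12.ravel(),
                "P22": self.p22.ravel(),
                "c": self.c.ravel(),
            }
        )


def additive_coefficient(probs: OriginProb) -> np.ndarray:
    """``c = P11 - P22``, elementwise over animals x positions."""
    return probs.p11 - probs.p22


def _two_flank_table(r1: float, r2: float) -> np.ndarray:
    """Origin-state distribution at an interior point given both flanks.

    Returns a ``(9, 3)`` array mapping flanking genotype codes
    ``gL * 3 + gR`` to ``(P11, P12, P22)``.  Computed by enumerating, per
    gamete, the phase-consistent flanking-allele assignments weighted by
    Haldane transmission probabilities, then convolving the two independent
    gametes.
    """
    r12 = r1 + r2 - 2.0 * r1 * r2  # Haldane: no interference
    # P(interior allele is D | gamete alleles at the two flanks)
    p_mid = {
        (1, 1): (1 - r1) * (1 - r2) / (1 - r12),
        (1, 0): (1 - r1) * r2 / r12 if r12 > 0 else 0.0,
        (0, 1): r1 * (1 - r2) / r12 if r12 > 0 else 0.0,
        (0, 0): r1 * r2 / (1 - r12),
    }
    trans = {  # per-gamete weight of a flank-allele pair (0.5 = start allele)
        (1, 1): 0.5 * (1 - r12),
        (1, 0): 0.5 * r12,
        (0, 1): 0.5 * r12,
        (0, 0): 0.5 * (1 - r12),
    }
    assign = {  # genotype code -> possible (gamete1, gamete2) allele pairs
        CODE_DD: [(1, 1)],
        CODE_DP: [(1, 0), (0, 1)],
        CODE_PP: [(0, 0)],
    }
    out = np.zeros((9, 3))
    for gl in (0, 1, 2):
        for gr in (0, 1, 2):
            p11 = p12 = p22 = wtot = 0.0
            for al1, al2 in assign[gl]:
                for ar1, ar2 in assign[gr]:
                    w = trans[(al1, ar1)] * trans[(al2, ar2)]
                    q1, q2 = p_mid[(al1, ar1)], p_mid[(al2, ar2)]
                    p11 += w * q1 * q2
                    p22 += w * (1 - q1) * (1 - q2)
                    p12 += w * (q1 * (1 - q2) + (1 - q1) * q2)
                    wtot += w
            out[gl * 3 + gr] = (p11 / wtot, p12 / wtot, p22 / wtot)
    return out


def _one_flank_table(r: float) -> np.ndarray:
    """``(3, 3)`` array mapping a single flanking genotype code to
    ``(P11, P12, P22)`` at distance with recombination fraction ``r``."""
    out = np.zeros((3, 3))
    for g in (0, 1, 2):
        if g == CODE_DD:
            qs = (1 - r, 1 - r)
        elif g == CODE_PP:
            qs = (r, r)
        else:
            qs = (1 - r, r)
        q1, q2 = qs
        out[g] = (q1 * q2, q1 * (1 - q2) + (1 - q1) * q2, (1 - q1) * (1 - q2))
    return out


def _codes_matrix(genotypes: pd.DataFrame, marker_order: Sequence[str]) -> np.ndarray:
    missing = [m for m in marker_order if m not in genotypes.columns]
    if missing:
        raise ValueError(f"genotypes missing markers: {missing[:5]}")
    g = genotypes.loc[:, list(marker_order)]
    if g.dtypes.apply(lambda d: d == object).any():
        codes = g.apply(
            lambda col: col.map(lambda v: CODE_OF_STATE.get(v, -1) if isinstance(v, str) else (-1 if pd.isna(v) else int(v)))
        ).to_numpy(dtype=int)
    else:
        arr = g.to_numpy(dtype=float)
        codes = np.where(np.isnan(arr), -1, arr).astype(int)
    if not np.isin(codes, (-1, 0, 1, 2)).all():
        raise ValueError("genotype codes must be in {0, 1, 2} or DD/DP/PP")
    return codes


def origin_probabilities(
    genotypes: pd.DataFrame,
    marker_map: MarkerMap,
    grid: EvaluationGrid,
    on_missing: str = "flank",
) -> OriginProb:
    """Breed-of-origin probabilities at every grid position.

    At marker positions with an observed genotype the probabilities are the
    0/1 indicators of the observed state.  At pseudo-positions they are the
    conditional distribution of the F2 origin state given the two flanking
    marker states, computed per gamete with Haldane recombination fractions
    and multiplied across the two independent gametes.

    Parameters
    ----------
    genotypes : animals x markers table; entries are ``DD``/``DP``/``PP``
        strings or integer D-allele counts 0/1/2; NaN marks missing.
    on_missing : ``"flank"`` (default) conditions on whichever single flank
        is observed (uniform ``(1/4, 1/2, 1/4)`` when neither is);
        ``"drop"`` yields NaN probabilities at affected positions.
    """
    if on_missing not in ("flank", "drop"):
        raise ValueError("on_missing must be 'flank' or 'drop'")
    n = len(genotypes)
    P = grid.n_positions
    p11 = np.full((n, P), np.nan)
    p12 = np.full((n, P), np.nan)
    p22 = np.full((n, P), np.nan)
    uniform = np.array([0.25, 0.5, 0.25])

    col_of = {m: i for i, m in enumerate(marker_map.table["marker"])}
    codes = _codes_matrix(genotypes, list(marker_map.table["marker"]))

    for g in marker_map.groups:
        sub = marker_map.markers_of(g)
        mcols = [col_of[m] for m in sub["marker"]]
        mcm = sub["cm"].to_numpy(dtype=float)
        gsub = grid.table[grid.table["group"] == g]
        for _, row in gsub.iterrows():
            j = int(row["index"])
            cm = float(row["cm"])
            if row["kind"] == "marker":
                i_m = int(np.argmin(np.abs(mcm - cm)))
                obs = codes[:, mcols[i_m]]
                ok = obs >= 0
                p11[ok, j] = (obs[ok] == CODE_DD).astype(float)
                p12[ok, j] = (obs[ok] == CODE_DP).astype(float)
                p22[ok, j] = (obs[ok] == CODE_PP).astype(float)
                if (~ok).any():
                    if on_missing == "drop":
                        continue
                    left = i_m - 1 if i_m > 0 else None
                    right = i_m + 1 if i_m + 1 < len(mcm) else None
                    _fill_conditioned(
                        p11, p12, p22, j, ~ok, codes, mcols, mcm, cm,
                        left, right, uniform,
                    )
            else:
                left = int(np.searchsorted(mcm, cm) - 1)
                right = left + 1
                any_missing = (codes[:, mcols[left]] < 0) | (codes[:, mcols[right]] < 0)
                both = ~any_missing
                if both.any():
                    tab = _two_flank_table(
                        float(haldane(cm - mcm[left])), float(haldane(mcm[right] - cm))
                    )
                    key = codes[both, mcols[left]] * 3 + codes[both, mcols[right]]
                    p11[both, j], p12[both, j], p22[both, j] = tab[key].T
                if any_missing.any() and on_missing == "flank":
                    _fill_conditioned(
                        p11, p12, p22, j, any_missing, codes, mcols, mcm, cm,
                        left, right, uniform,
                    )
    return OriginProb(pd.Index(genotypes.index), grid, p11, p12, p22)


def _fill_conditioned(p11, p12, p22, j, mask, codes, mcols, mcm, cm, left, right, uniform):
    """Single-flank fallback for animals in ``mask`` at grid column ``j``."""
    idx = np.where(mask)[0]
    gl = codes[idx, mcols[left]] if left is not None else np.full(len(idx), -1)
    gr = codes[idx, mcols[right]] if right is not None else np.full(len(idx), -1)
    tabs = {}
    for a, l, r in zip(idx, gl, gr):
        if l >= 0 and r >= 0:
            key = ("two",)
            if key not in tabs:
                tabs[key] = _two_flank_table(
                    float(haldane(cm - mcm[left])), float(haldane(mcm[right] - cm))
                )
            p11[a, j], p12[a, j], p22[a, j] = tabs[key][l * 3 + r]
        elif l >= 0:
            key = ("l",)
            if key not in tabs:
                tabs[key] = _one_flank_table(float(haldane(abs(cm - mcm[left]))))
            p11[a, j], p12[a, j], p22[a, j] = tabs[key][l]
        elif r >= 0:
            key = ("r",)
            if key not in tabs:
                tabs[key] = _one_flank_table(float(haldane(abs(mcm[right] - cm))))
            p11[a, j], p12[a, j], p22[a, j] = tabs[key][r]
        else:
            p11[a, j], p12[a, j], p22[a, j] = uniform
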