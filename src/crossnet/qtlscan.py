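"""Whole-genome pQTL and eQTL scans for an F2 line cross.

Phenotype scan (pQTL): at every grid position the trait is regressed on
sex, slaughter group and carcass weight plus the additive breed-origin
coefficient ``c``; the QTL term is tested with the exact F-test comparing
the full and reduced ordinary-least-squares fits.  Genome-wise significance
is controlled per trait with a permutation test on the maximum F statistic
(genotype rows are permuted jointly across the genome, trait and covariates
stay fixed).

Expression scan (eQTL): each probe's log2 intensity is modelled with dye
and sex as fixed effects, the hybridisation array as a Gaussian random
effect, and the QTL coefficient ``c``; the QTL term is tested by a
likelihood-ratio test between maximum-likelihood fits (ML, not REML,
because the fixed-effect structures differ) against chi-square with one
degree of freedom, with Benjamini-Hochberg control across the whole
probe x position family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .genomap import EvaluationGrid, OriginProb

__all__ = [
    "covariate_matrix",
    "fit_pqtl_position",
    "scan_phenotype",
    "permutation_threshold",
    "PhenotypeScan",
    "PhenotypeScanResults",
    "MixedModelFit",
    "fit_eqtl_position",
    "bh_adjust",
    "scan_expression",
    "ExpressionScan",
    "ExpressionScanResults",
]

_VAR_TOL = 1e-12


def covariate_matrix(
    trait_table: pd.DataFrame,
    factors: Sequence[str] = ("sex", "group"),
    covariates: Sequence[str] = ("carcwt",),
) -> np.ndarray:
    """Design matrix: intercept + dummy-coded factors + linear covariates.

    Factors with fewer than two observed levels are dropped with a warning
    (they are confounded with the intercept).
    """
    n = len(trait_table)
    cols = [np.ones(n)]
    for f in factors:
        if f not in trait_table.columns:
            continue
        series = trait_table[f]
        if series.isna().any():
            bad = series.index[series.isna()][0]
            raise ValueError(f"missing covariate {f!r} for animal {bad!r}")
        levels = pd.unique(series)
        if len(levels) < 2:
            warnings.warn(f"factor {f!r} has < 2 levels; dropped")
            continue
        d = pd.get_dummies(series, drop_first=True).to_numpy(dtype=float)
        cols.append(d)
    for cvr in covariates:
        if cvr not in trait_table.columns:
            continue
        v = trait_table[cvr].to_numpy(dtype=float)
        if np.isnan(v).any():
            bad = trait_table.index[np.isnan(v)][0]
            raise ValueError(f"missing covariate {cvr!r} for animal {bad!r}")
        cols.append(v[:, None] if v.ndim == 1 else v)
    return np.column_stack(cols)


def _residualize(Z: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residuals of the columns of ``M`` after OLS on ``Z``."""
    beta, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ beta


def fit_pqtl_position(
    y: np.ndarray, covars: np.ndarray, c: np.ndarray
) -> tuple[float, float, float]:
    """Exact F-test for the additive QTL effect at one position.

    Compares ``y = covars @ beta + c * alpha + e`` with the reduced model
    without the QTL term; returns ``(F, p, alpha_hat)``.  A position where
    ``c`` is (conditionally) constant is untestable and yields NaNs.
    """
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    n = len(y)
    rank_z = np.linalg.matrix_rank(covars)
    ey = _residualize(covars, y[:, None])[:, 0]
    ec = _residualize(covars, c[:, None])[:, 0]
    sxx = float(ec @ ec)
    if sxx < _VAR_TOL * n:
        return (np.nan, np.nan, np.nan)
    df = n - rank_z - 1
    if df <= 0:
        raise ValueError("not enough observations for the full model")
    alpha = float(ec @ ey) / sxx
    rss_red = float(ey @ ey)
    if rss_red < _VAR_TOL * n:  # constant trait (given covariates): untestable
        return (np.nan, np.nan, np.nan)
    rss_full = rss_red - alpha * alpha * sxx
    F = (rss_red - rss_full) / (rss_full / df) if rss_full > 0 else np.inf
    p = float(stats.f.sf(F, 1, df)) if np.isfinite(F) else 0.0
    return (float(F), p, alpha)


def _scan_stats(ey, EC, df):
    """Vectorised per-position F, p and alpha from residualised y and c."""
    sxx = np.einsum("ij,ij->j", EC, EC)
    sxy = ey @ EC
    n = len(ey)
    if float(ey @ ey) < _VAR_TOL * n:  # constant trait: nothing to test
        nanv = np.full(EC.shape[1], np.nan)
        return nanv, nanv.copy(), nanv.copy()
    testable = sxx > _VAR_TOL * n
    alpha = np.full(EC.shape[1], np.nan)
    F = np.full(EC.shape[1], np.nan)
    alpha[testable] = sxy[testable] / sxx[testable]
    rss_red = float(ey @ ey)
    ssr = np.zeros(EC.shape[1])
    ssr[testable] = alpha[testable] * sxy[testable]
    rss_full = rss_red - ssr
    with np.errstate(divide="ignore", invalid="ignore"):
        F[testable] = ssr[testable] / (rss_full[testable] / df)
    p = np.full(EC.shape[1], np.nan)
    p[testable] = stats.f.sf(F[testable], 1, df)
    return F, p, alpha


def scan_phenotype(
    trait_table: pd.DataFrame,
    trait: str,
    probs: OriginProb,
    grid: EvaluationGrid | None = None,
) -> pd.DataFrame:
    """F-test the additive QTL effect at every grid position for one trait.

    Returns the grid table augmented with ``F``, ``p`` and ``alpha``
    columns.  Equivalent to :func:`fit_pqtl_position` per position but
    computed through a single residualisation of the trait and of all
    ``c`` columns against the covariates (Frisch-Waugh).
    """
    grid = probs.grid if grid is None else grid
    if not trait_table.index.equals(pd.Index(probs.animals)):
        trait_table = trait_table.loc[probs.animals]
    y = trait_table[trait].to_numpy(dtype=float)
    Z = covariate_matrix(trait_table)
    df = len(y) - np.linalg.matrix_rank(Z) - 1
    C = np.nan_to_num(probs.c, nan=0.0)
    ey = _residualize(Z, y[:, None])[:, 0]
    EC = _residualize(Z, C)
    F, p, alpha = _scan_stats(ey, EC, df)
    out = grid.table.copy()
    out["F"] = F
    out["p"] = p
    out["alpha"] = alpha
    return out


def permutation_threshold(
    trait_table: pd.DataFrame,
    trait: str,
    probs: OriginProb,
    n_perm: int = 1000,
    level: float = 0.05,
    seed: int | np.random.Generator | None = None,
    return_null: bool = False,
    permutations: Sequence[np.ndarray] | None = None,
):
    """Genome-wise F threshold from the permutation null of the maximum F.

    Each permutation shuffles the animal-to-genotype mapping jointly across
    all grid positions while the trait and its covariates stay in place
    (Churchill-Doerge style), preserving any covariate-trait association
    under the no-QTL null.  The threshold is the empirical ``1 - level``
    quantile (type-7 linear interpolation) of the max-F null distribution.

    ``permutations`` overrides the random draws with an explicit list of
    index arrays (e.g. the exhaustive permutation group for tiny n).
    """
    if permutations is not None:
        n_perm = len(permutations)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 1 / level:
        warnings.warn(
            f"n_perm = {n_perm} is small for level {level}; threshold will be coarse"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if not trait_table.index.equals(pd.Index(probs.animals)):
        trait_table = trait_table.loc[probs.animals]
    y = trait_table[trait].to_numpy(dtype=float)
    Z = covariate_matrix(trait_table)
    df = len(y) - np.linalg.matrix_rank(Z) - 1
    C = np.nan_to_num(probs.c, nan=0.0)
    ey = _residualize(Z, y[:, None])[:, 0]
    zpinv = np.linalg.pinv(Z)
    max_f = np.empty(n_perm)
    n = len(y)
    for b in range(n_perm):
        perm = (
            np.asarray(permutations[b]) if permutations is not None else rng.permutation(n)
        )
        Cp = C[perm]
        ECp = Cp - Z @ (zpinv @ Cp)
        F, _, _ = _scan_stats(ey, ECp, df)
        max_f[b] = np.nanmax(F)
    thr = float(np.quantile(max_f, 1.0 - level, method="linear"))
    return (thr, max_f) if return_null else thr


@dataclass
class PhenotypeScanResults:
    """Per-trait scan tables and genome-wise thresholds."""

    tables: dict
    thresholds: dict
    level: float

    def significant(self, trait: str) -> pd.DataFrame:
        t = self.tables[trait]
        return t[t["F"] >= self.thresholds[trait]]

    def peak(self, trait: str) -> pd.Series:
        t = self.tables[trait]
        return t.loc[t["F"].idxmax()]

    def summary(self) -> pd.DataFrame:
        rows = []
        for trait, t in self.tables.items():
            pk = t.loc[t["F"].idxmax()]
            rows.append(
                {
                    "trait": trait,
                    "peak_group": pk["group"],
                    "peak_cm": pk["cm"],
                    "peak_index": int(pk["index"]),
                    "max_F": pk["F"],
                    "p": pk["p"],
                    "alpha": pk["alpha"],
                    "threshold": self.thresholds[trait],
                    "significant": bool(pk["F"] >= self.thresholds[trait]),
                }
            )
        return pd.DataFrame(rows)


class PhenotypeScan:
    """Genome scan model for one or more phenotypes.

    ``fit`` runs the per-position F-tests and the per-trait permutation
    thresholds and returns a :class:`PhenotypeScanResults`.
    """

    def __init__(
        self,
        trait_table: pd.DataFrame,
        probs: OriginProb,
        traits: Sequence[str] | None = None,
    ):
        self.trait_table = trait_table
        self.probs = probs
        reserved = {"sex", "group", "carcwt"}
        self.traits = (
            list(traits)
            if traits is not None
            else [c for c in trait_table.columns if c not in reserved]
        )

    def fit(
        self, n_perm: int = 1000, level: float = 0.05, seed: int | None = None
    ) -> PhenotypeScanResults:
        ss = np.random.SeedSequence(seed)
        tables, thresholds = {}, {}
        for trait, child in zip(self.traits, ss.spawn(len(self.traits))):
            tables[trait] = scan_phenotype(self.trait_table, trait, self.probs)
            thresholds[trait] = permutation_threshold(
                self.trait_table,
                trait,
                self.probs,
                n_perm=n_perm,
                level=level,
                seed=np.random.default_rng(child),
            )
        return PhenotypeScanResults(tables=tables, thresholds=thresholds, level=level)


# ---------------------------------------------------------------------------
# eQTL mixed model


@dataclass
class MixedModelFit:
    """ML fit of a Gaussian model with one random (array) effect."""

    loglik: float
    beta: np.ndarray
    sigma2_e: float
    ratio: float  # sigma2_array / sigma2_e
    boundary: bool  # ratio pinned at zero -> plain OLS


class _ArrayTransform:
    """Orthogonal whitening basis for a single random array effect.

    With arrays of at most two animals, rotating each pair into its mean
    and difference components diagonalises ``V = I + ratio * Z Z'``: the
    pair-mean component has variance ``1 + 2 ratio``, the pair-difference
    component variance 1, and singleton arrays variance ``1 + ratio``.  ML
    fitting then reduces to weighted least squares plus a one-dimensional
    profile over the variance ratio.
    """

    def __init__(self, arrays: pd.Series):
        n = len(arrays)
        rows = []
        kinds = []  # 2 animals share variance factor, 1 alone, 0 none
        s = 1.0 / np.sqrt(2.0)
        idx_of = {a: i for i, a in enumerate(arrays.index)}
        for a, members in arrays.groupby(arrays).groups.items():
            ids = [idx_of[m] for m in members]
            if len(ids) == 2:
                r1 = np.zeros(n)
                r1[ids[0]] = s
                r1[ids[1]] = s
                r2 = np.zeros(n)
                r2[ids[0]] = s
                r2[ids[1]] = -s
                rows += [r1, r2]
                kinds += [2, 0]
            elif len(ids) == 1:
                r = np.zeros(n)
                r[ids[0]] = 1.0
                rows.append(r)
                kinds.append(1)
            else:
                raise ValueError(
                    f"array {a!r} has {len(ids)} animals; at most 2 supported"
                )
        self.U = np.vstack(rows)
        self.kind = np.asarray(kinds)

    def variances(self, ratio: float) -> np.ndarray:
        d = np.ones(len(self.kind))
        d[self.kind == 2] = 1.0 + 2.0 * ratio
        d[self.kind == 1] = 1.0 + ratio
        return d


def _profile_loglik(ratio, Uy, UX, tr: _ArrayTransform):
    d = tr.variances(ratio)
    w = 1.0 / np.sqrt(d)
    beta, *_ = np.linalg.lstsq(UX * w[:, None], Uy * w, rcond=None)
    resid = (Uy - UX @ beta) * w
    n = len(Uy)
    rss = float(resid @ resid)
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2 * np.pi) + 1.0) - 0.5 * n * np.log(sigma2) - 0.5 * float(
        np.sum(np.log(d))
    )
    return ll, beta, sigma2


def fit_mixed_ml(
    y: np.ndarray,
    X: np.ndarray,
    arrays: pd.Series,
    transform: _ArrayTransform | None = None,
    max_ratio: float = 1e3,
) -> MixedModelFit:
    """Maximum-likelihood fit of ``y = X beta + array + e``.

    The array-to-error variance ratio is profiled out by one-dimensional
    bounded optimisation (tolerance 1e-8) around a closed-form GLS inner
    step; a ratio estimate at the zero boundary collapses the model to OLS
    and is flagged.
    """
    tr = transform if transform is not None else _ArrayTransform(arrays)
    Uy = tr.U @ np.asarray(y, dtype=float)
    UX = tr.U @ X
    res = optimize.minimize_scalar(
        lambda r: -_profile_loglik(r, Uy, UX, tr)[0],
        bounds=(0.0, max_ratio),
        method="bounded",
        options={"xatol": 1e-8},
    )
    ratio = float(res.x)
    ll0, beta0, s0 = _profile_loglik(0.0, Uy, UX, tr)
    ll, beta, s2 = _profile_loglik(ratio, Uy, UX, tr)
    if ll0 >= ll:
        ratio, ll, beta, s2 = 0.0, ll0, beta0, s0
    return MixedModelFit(
        loglik=float(ll),
        beta=beta,
        sigma2_e=float(s2),
        ratio=ratio,
        boundary=ratio < 1e-6,
    )


def fit_eqtl_position(
    w: np.ndarray,
    design: pd.DataFrame,
    c: np.ndarray,
    transform: _ArrayTransform | None = None,
    X_red: np.ndarray | None = None,
    ll_red: float | None = None,
) -> tuple[float, float, float]:
    """Likelihood-ratio test for the additive eQTL effect at one position.

    ``w = mu + dye + sex + c * alpha + array(random) + e`` fitted by ML is
    compared with the reduced model without the QTL term; the statistic is
    referred to chi-square with 1 df.  Returns ``(LRT, p, alpha_hat)``.
    """
    if X_red is None:
        X_red = covariate_matrix(design, factors=("dye", "sex"), covariates=())
    tr = transform if transform is not None else _ArrayTransform(design["array"])
    c = np.asarray(c, dtype=float)
    ec = _residualize(X_red, c[:, None])[:, 0]
    if float(ec @ ec) < _VAR_TOL * len(c):
        return (np.nan, np.nan, np.nan)
    if ll_red is None:
        ll_red = fit_mixed_ml(w, X_red, design["array"], transform=tr).loglik
    X_full = np.column_stack([X_red, c])
    full = fit_mixed_ml(w, X_full, design["array"], transform=tr)
    lrt = max(0.0, 2.0 * (full.loglik - ll_red))
    p = float(stats.chi2.sf(lrt, 1))
    return (float(lrt), p, float(full.beta[-1]))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1.

    NaN entries are excluded from the family (with a warning) and returned
    as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} NaN p-values excluded from BH")
    if ok.any():
        if (flat[ok] < 0).any() or (flat[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        q = multipletests(flat[ok], method="fdr_bh")[1]
        tmp = out.ravel()
        tmp[ok] = q
        out = tmp.reshape(p.shape)
    return out


@dataclass
class ExpressionScanResults:
    """Per-probe eQTL scan tables with family-wide BH q-values."""

    tables: dict  # probe -> grid table with LRT, p, alpha, q
    best: pd.DataFrame  # one row per probe: best position and its q
    fdr_level: float

    def significant(self) -> pd.DataFrame:
        return self.best[self.best["q"] <= self.fdr_level]

    def summary(self) -> pd.DataFrame:
        return self.best


class ExpressionScan:
    """Genome eQTL scan model over a probe x animal expression matrix."""

    def __init__(
        self,
        expression: pd.DataFrame,
        design: pd.DataFrame,
        probs: OriginProb,
        probes: Sequence[str] | None = None,
    ):
        if not design.index.equals(pd.Index(probs.animals)):
            design = design.loc[probs.animals]
        self.expression = expression.loc[:, probs.animals]
        self.design = design
        self.probs = probs
        self.probes = list(probes) if probes is not None else list(expression.index)

    def fit(self, fdr_level: float = 0.20) -> ExpressionScanResults:
        tr = _ArrayTransform(self.design["array"])
        X_red = covariate_matrix(self.design, factors=("dye", "sex"), covariates=())
        C = np.nan_to_num(self.probs.c, nan=0.0)
        grid_table = self.probs.grid.table
        tables = {}
        for probe in self.probes:
            w = self.expression.loc[probe].to_numpy(dtype=float)
            ll_red = fit_mixed_ml(w, X_red, self.design["array"], transform=tr).loglik
            stats_rows = np.empty((C.shape[1], 3))
            for j in range(C.shape[1]):
                stats_rows[j] = fit_eqtl_position(
                    w, self.design, C[:, j], transform=tr, X_red=X_red, ll_red=ll_red
                )
            t = grid_table.copy()
            t["LRT"], t["p"], t["alpha"] = stats_rows.T
            tables[probe] = t
        all_p = np.concatenate([tables[pr]["p"].to_numpy() for pr in self.probes])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            all_q = bh_adjust(all_p)
        best_rows = []
        off = 0
        for probe in self.probes:
            t = tables[probe]
            t["q"] = all_q[off : off + len(t)]
            off += len(t)
            if t["p"].notna().any():
                i = t["p"].idxmin()
                row = t.loc[i]
                best_rows.append(
                    {
                        "probe": probe,
                        "group": row["group"],
                        "cm": row["cm"],
                        "index": int(row["index"]),
                        "LRT": row["LRT"],
                        "p": row["p"],
                        "alpha": row["alpha"],
                        "q": row["q"],
                    }
                )
        best = pd.DataFrame(best_rows)
        return ExpressionScanResults(tables=tables, best=best, fdr_level=fdr_level)


def scan_expression(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    probs: OriginProb,
    fdr_level: float = 0.20,
) -> ExpressionScanResults:
    """Functional wrapper around :class:`ExpressionScan`."""
    return ExpressionScan(expression, design, probs).fit(fdr_level=fdr_level)
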