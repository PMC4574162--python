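"""pQTL F-tests, permutation thresholds, eQTL mixed-model LRTs, BH FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossnet import qtlscan
from crossnet.qtlscan import (
    ExpressionScan,
    PhenotypeScan,
    _ArrayTransform,
    bh_adjust,
    covariate_matrix,
    fit_eqtl_position,
    fit_mixed_ml,
    fit_pqtl_position,
    permutation_threshold,
    scan_phenotype,
)
from crossnet.simcross import SimConfig, TrueDAG, simulate_study
from crossnet import genomap


def make_trait_table(rng, n):
    return pd.DataFrame(
        {
            "sex": rng.choice(["F", "M"], n),
            "group": rng.choice(["G1", "G2", "G3"], n),
            "carcwt": rng.normal(85, 7, n),
        },
        index=pd.Index([f"A{i}" for i in range(n)], name="animal_id"),
    )


def two_ols_oracle(y, Z, c):
    """Independent F-test oracle: fit both models by explicit normal
    equations and apply the textbook F formula."""
    Zf = np.column_stack([Z, c])
    bf = np.linalg.solve(Zf.T @ Zf, Zf.T @ y)
    br = np.linalg.solve(Z.T @ Z, Z.T @ y)
    rss_f = np.sum((y - Zf @ bf) ** 2)
    rss_r = np.sum((y - Z @ br) ** 2)
    df = len(y) - Zf.shape[1]
    F = (rss_r - rss_f) / (rss_f / df)
    return F, stats.f.sf(F, 1, df), bf[-1]


class TestPqtlPosition:
    def test_matches_two_ols_oracle(self):
        rng = np.random.default_rng(30)
        n = 30
        tt = make_trait_table(rng, n)
        tt["y"] = rng.normal(size=n)
        c = rng.choice([-1.0, 0.0, 1.0], n)
        Z = covariate_matrix(tt)
        F, p, a = fit_pqtl_position(tt["y"].to_numpy(), Z, c)
        Fo, po, ao = two_ols_oracle(tt["y"].to_numpy(), Z, c)
        assert F == pytest.approx(Fo, rel=1e-10)
        assert p == pytest.approx(po, rel=1e-10)
        assert a == pytest.approx(ao, rel=1e-10)

    def test_perfect_fit(self):
        rng = np.random.default_rng(1)
        n = 40
        tt = make_trait_table(rng, n)
        c = rng.choice([-1.0, 0.0, 1.0], n)
        y = 2.0 * c
        # remove factor columns so y really is exactly 2c given covariates
        Z = np.ones((n, 1))
        F, p, a = fit_pqtl_position(y, Z, c)
        assert a == pytest.approx(2.0, abs=1e-10)
        assert p < 1e-12

    def test_constant_c_untestable(self):
        rng = np.random.default_rng(2)
        n = 25
        tt = make_trait_table(rng, n)
        y = rng.normal(size=n)
        F, p, a = fit_pqtl_position(y, covariate_matrix(tt), np.ones(n))
        assert np.isnan(F) and np.isnan(p)

    def test_null_pvalues_uniform(self):
        """Exact F-test: p-values uniform under the null (KS at alpha=0.01)."""
        rng = np.random.default_rng(3)
        n, reps = 40, 5000
        tt = make_trait_table(rng, n)
        Z = covariate_matrix(tt)
        c = rng.choice([-1.0, 0.0, 1.0], n)
        # vectorised: residualise c once, then many independent traits
        from crossnet.qtlscan import _residualize, _scan_stats

        ec = _residualize(Z, c[:, None])
        Y = rng.normal(size=(n, reps))
        EY = _residualize(Z, Y)
        df = n - np.linalg.matrix_rank(Z) - 1
        ps = np.empty(reps)
        for i in range(reps):
            _, p, _ = _scan_stats(EY[:, i], ec, df)
            ps[i] = p[0]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestScanPhenotype:
    def test_scan_equals_positionwise_fit(self, small_study, small_probs):
        table = scan_phenotype(small_study.trait_table, "BF10", small_probs)
        Z = covariate_matrix(small_study.trait_table)
        y = small_study.trait_table["BF10"].to_numpy()
        for j in [0, 17, 100, 250]:
            F, p, a = fit_pqtl_position(y, Z, small_probs.c[:, j])
            assert table["F"].iloc[j] == pytest.approx(F, rel=1e-9)
            assert table["alpha"].iloc[j] == pytest.approx(a, rel=1e-9)

    def test_peak_near_true_qtl(self, small_study, small_probs):
        table = scan_phenotype(small_study.trait_table, "FAT", small_probs)
        peak = int(table.loc[table["F"].idxmax(), "index"])
        assert abs(peak - small_study.truth.qtl_grid_index) <= 5

    def test_constant_trait_all_untestable(self, small_study, small_probs):
        tt = small_study.trait_table.copy()
        tt["flat"] = 1.0
        table = scan_phenotype(tt, "flat", small_probs)
        assert table["F"].isna().all()


class TestPermutationThreshold:
    def test_exhaustive_enumeration_oracle(self):
        """n = 5 animals: running the operation with all 120 distinct
        permutations equals an explicit exhaustive-enumeration oracle."""
        rng = np.random.default_rng(8)
        n = 5
        tt = pd.DataFrame(
            {"sex": ["F", "M", "F", "M", "F"], "group": "G1", "carcwt": rng.normal(85, 7, n)},
            index=pd.Index([f"A{i}" for i in range(n)], name="animal_id"),
        )
        tt["y"] = rng.normal(size=n)
        grid = genomap.build_grid(
            genomap.MarkerMap(
                pd.DataFrame(
                    {"group": "LG1", "marker": ["m1", "m2"], "cm": [0.0, 20.0]}
                )
            ),
            k=1,
        )
        C = rng.choice([-1.0, 0.0, 1.0], size=(n, grid.n_positions))
        probs = genomap.OriginProb(
            pd.Index(tt.index),
            grid,
            p11=(C == 1).astype(float),
            p12=(C == 0).astype(float),
            p22=(C == -1).astype(float),
        )
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        thr = permutation_threshold(
            tt, "y", probs, level=0.05, permutations=perms
        )
        # oracle: per permutation, max F over positions via the single-
        # position fit; type-7 quantile
        Z = covariate_matrix(tt)
        y = tt["y"].to_numpy()
        max_f = []
        for p in perms:
            fs = [
                fit_pqtl_position(y, Z, probs.c[list(p), j])[0]
                for j in range(grid.n_positions)
            ]
            max_f.append(np.nanmax(fs))
        assert thr == pytest.approx(np.quantile(max_f, 0.95), rel=1e-9)

    def test_threshold_monotone_in_level(self, small_study, small_probs):
        rng = np.random.default_rng(0)
        perms = [rng.permutation(len(small_study.trait_table)) for _ in range(60)]
        thr05 = permutation_threshold(
            small_study.trait_table, "BF10", small_probs, level=0.05, permutations=perms
        )
        thr10 = permutation_threshold(
            small_study.trait_table, "BF10", small_probs, level=0.10, permutations=perms
        )
        assert thr05 >= thr10

    def test_relabeling_invariance(self, small_study, small_probs):
        """Jointly permuting animals in trait table and genotypes leaves the
        threshold unchanged when the same permutation list is used."""
        n = len(small_study.trait_table)
        rng = np.random.default_rng(1)
        perms = [rng.permutation(n) for _ in range(40)]
        thr = permutation_threshold(
            small_study.trait_table, "LOIN", small_probs, permutations=perms
        )
        relab = rng.permutation(n)
        tt2 = small_study.trait_table.iloc[relab]
        probs2 = genomap.OriginProb(
            pd.Index(tt2.index),
            small_probs.grid,
            small_probs.p11[relab],
            small_probs.p12[relab],
            small_probs.p22[relab],
        )
        inv = np.argsort(relab)
        perms2 = [inv[np.asarray(p)][relab] for p in perms]
        # mapping of permutations under relabeling: pi' = relab^-1 . pi . relab
        thr2 = permutation_threshold(tt2, "LOIN", probs2, permutations=perms2)
        assert thr2 == pytest.approx(thr, rel=1e-9)

    def test_small_nperm_warns(self, small_study, small_probs):
        with pytest.warns(UserWarning, match="small"):
            permutation_threshold(
                small_study.trait_table, "BF10", small_probs, n_perm=5, seed=0
            )


class TestBH:
    def test_hand_examples(self):
        assert np.allclose(bh_adjust(np.ones(4)), 1.0)
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_p_is_identity(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_matches_brute_force_oracle(self):
        def brute(p):
            m = len(p)
            order = np.argsort(p, kind="stable")
            q = np.empty(m)
            # step-up: q_i = min over j with p_j >= p_i of m p_j / rank_j
            ranked = p[order]
            for i in range(m):
                cands = [
                    m * ranked[j] / (j + 1) for j in range(m) if ranked[j] >= ranked[i]
                ]
                q[order[i]] = min(1.0, min(cands))
            return q

        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute(p), atol=1e-12)

    def test_nan_handling(self):
        with pytest.warns(UserWarning, match="NaN"):
            q = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(6)
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def expr_design(rng, n):
    order = rng.permutation(n)
    design = pd.DataFrame(
        index=pd.Index([f"A{i}" for i in range(n)], name="animal_id"),
        columns=["array", "dye", "sex"],
    )
    for k in range(0, n, 2):
        design.iloc[order[k]] = [f"AR{k // 2}", "cy3", rng.choice(["F", "M"])]
        if k + 1 < n:
            design.iloc[order[k + 1]] = [f"AR{k // 2}", "cy5", rng.choice(["F", "M"])]
    return design


def grid_profile_oracle(y, X, design, ratios):
    """Independent ML oracle: profile the likelihood over a dense grid of
    the array-variance ratio, building V explicitly per grid point."""
    Zmat = pd.get_dummies(design["array"]).to_numpy(dtype=float)
    n = len(y)
    best = -np.inf
    for lam in ratios:
        V = np.eye(n) + lam * Zmat @ Zmat.T
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        s2 = float(r @ Vi @ r) / n
        ll = (
            -0.5 * n * (np.log(2 * np.pi) + 1)
            - 0.5 * n * np.log(s2)
            - 0.5 * np.linalg.slogdet(V)[1]
        )
        best = max(best, ll)
    return best


class TestMixedModel:
    def test_loglik_matches_grid_profile_oracle(self):
        rng = np.random.default_rng(11)
        n = 40
        design = expr_design(rng, n)
        X = covariate_matrix(design, factors=("dye", "sex"), covariates=())
        arr_eff = {a: rng.normal(0, 0.7) for a in design["array"].unique()}
        y = (
            X @ rng.normal(size=X.shape[1])
            + design["array"].map(arr_eff).to_numpy(dtype=float)
            + rng.normal(size=n)
        )
        fit = fit_mixed_ml(y, X, design["array"])
        oracle = grid_profile_oracle(y, X, design, np.linspace(0, 5, 2001))
        assert fit.loglik >= oracle - 1e-6
        assert fit.loglik == pytest.approx(oracle, abs=1e-3)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.regression.mixed_linear_model as mlm

        rng = np.random.default_rng(12)
        n = 60
        design = expr_design(rng, n)
        X = covariate_matrix(design, factors=("dye", "sex"), covariates=())
        arr_eff = {a: rng.normal(0, 0.5) for a in design["array"].unique()}
        y = 1.0 + design["array"].map(arr_eff).to_numpy(dtype=float) + rng.normal(size=n)
        fit = fit_mixed_ml(y, X, design["array"])
        sm_fit = mlm.MixedLM(
            y, X, groups=design["array"].to_numpy()
        ).fit(reml=False)
        assert fit.loglik == pytest.approx(float(sm_fit.llf), abs=1e-4)

    def test_zero_array_variance_collapses_to_ols(self):
        """When the array variance estimate hits the zero boundary the
        mixed model reduces to OLS: same log-likelihood, same LRT.

        Residuals are constructed antisymmetric within every array pair, so
        the pair-mean residual variance cannot exceed the pair-difference
        variance and the ML ratio is exactly zero.
        """
        rng = np.random.default_rng(13)
        n = 40
        design = expr_design(rng, n)
        c = rng.choice([-1.0, 0.0, 1.0], n)
        noise = np.zeros(n)
        for _, members in design.groupby("array").groups.items():
            idx = [design.index.get_loc(m) for m in members]
            d = rng.normal()
            noise[idx[0]] = d
            if len(idx) > 1:
                noise[idx[1]] = -d
        y = 0.5 * c + noise
        X_red = covariate_matrix(design, factors=("dye", "sex"), covariates=())
        full = fit_mixed_ml(y, np.column_stack([X_red, c]), design["array"])
        assert full.boundary
        lrt, p, a = fit_eqtl_position(y, design, c)

        def ols_ll(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            s2 = np.sum((y - X @ beta) ** 2) / n
            return -0.5 * n * (np.log(2 * np.pi * s2) + 1)

        lrt_ols = 2 * (ols_ll(np.column_stack([X_red, c])) - ols_ll(X_red))
        assert lrt == pytest.approx(lrt_ols, abs=1e-6)

    def test_null_lrt_calibration(self):
        rng = np.random.default_rng(14)
        n, reps = 60, 400
        design = expr_design(rng, n)
        rejections = 0
        for _ in range(reps):
            c = rng.choice([-1.0, 0.0, 1.0], n)
            arr_eff = {a: rng.normal(0, 0.5) for a in design["array"].unique()}
            y = design["array"].map(arr_eff).to_numpy(dtype=float) + rng.normal(size=n)
            _, p, _ = fit_eqtl_position(y, design, c)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01


@pytest.fixture(scope="module")
def cis_scan():
    """Five strongly cis-regulated probes among 40 null probes on a
    small two-group map."""
    nodes = {"Q": "genotype"}
    nodes.update({f"C{i}": "expression" for i in range(1, 6)})
    dag = TrueDAG(
        nodes,
        [("Q", f"C{i}", 1.2) for i in range(1, 6)],
        {f"C{i}": 1.0 for i in range(1, 6)},
    )
    cfg = SimConfig(
        n_f2=150,
        map_spec=((80.0, 5), (80.0, 5)),
        qtl=("LG1", 40.0),
        true_dag=dag,
        n_null_probes=40,
        grid_k=3,
        seed=21,
    )
    study = simulate_study(cfg, seed=21)
    probs = genomap.origin_probabilities(
        study.genotypes.markers, study.marker_map, study.grid
    )
    res = ExpressionScan(study.expression, study.design, probs).fit(fdr_level=0.20)
    return study, res


class TestExpressionScan:
    def test_cis_probes_all_detected(self, cis_scan):
        study, res = cis_scan
        called = set(res.significant()["probe"])
        assert {f"C{i}" for i in range(1, 6)} <= called

    def test_all_null_expression_rarely_called(self):
        """Under a global null the BH step controls the family-wise chance
        of any call at the FDR level; with one seeded study we expect no
        more than a stray call or two."""
        dag = TrueDAG({"Q": "genotype"}, [], {})
        cfg = SimConfig(
            n_f2=120,
            map_spec=((80.0, 5),),
            qtl=("LG1", 40.0),
            true_dag=dag,
            n_null_probes=30,
            grid_k=3,
            seed=22,
        )
        study = simulate_study(cfg, seed=22)
        probs = genomap.origin_probabilities(
            study.genotypes.markers, study.marker_map, study.grid
        )
        res = ExpressionScan(study.expression, study.design, probs).fit(fdr_level=0.20)
        assert len(res.significant()) <= 2

    def test_best_position_near_qtl(self, cis_scan):
        study, res = cis_scan
        best = res.best.set_index("probe")
        for i in range(1, 6):
            assert abs(best.loc[f"C{i}", "index"] - study.truth.qtl_grid_index) <= 4

    def test_single_probe_single_position_q_equals_p(self):
        rng = np.random.default_rng(31)
        n = 40
        design = expr_design(rng, n)
        grid = genomap.build_grid(
            genomap.MarkerMap(
                pd.DataFrame({"group": ["LG1"], "marker": ["m1"], "cm": [0.0]})
            ),
            k=0,
        )
        C = rng.choice([-1.0, 0.0, 1.0], size=(n, 1))
        probs = genomap.OriginProb(
            pd.Index(design.index),
            grid,
            (C == 1).astype(float),
            (C == 0).astype(float),
            (C == -1).astype(float),
        )
        expr = pd.DataFrame(
            rng.normal(size=(1, n)), index=["probe1"], columns=design.index
        )
        res = ExpressionScan(expr, design, probs).fit()
        assert res.best["q"].iloc[0] == pytest.approx(res.best["p"].iloc[0])
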