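"""MME solutions, PEV/PEC, precorrection, population accuracy and EM-REML."""

import numpy as np
import pandas as pd
import pytest

from lrblup import (
    FixedDesign,
    Pedigree,
    RelationshipMatrix,
    VarianceComponents,
    accuracy_from_pev,
    build_nrm,
    em_reml,
    precorrect,
    solve_mme,
)
from conftest import redraw_phenotypes


def eye_K(n):
    return RelationshipMatrix([str(i + 1) for i in range(n)], np.eye(n))


VC = VarianceComponents(0.4, 0.6)


class TestSolveMME:
    def test_single_animal_mean_model(self):
        # hand-solved 2x2 system: mu + u = y and mu + (1+lambda) u = y
        phen = pd.DataFrame({"id": ["1"], "y": [3.7]})
        res = solve_mme(phen, FixedDesign(), eye_K(1), VC)
        assert res.beta_hat.iloc[0] == pytest.approx(3.7)
        assert res.u_hat.loc["1"] == pytest.approx(0.0, abs=1e-12)

    def test_unrelated_animals_are_ridge_shrunken(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 12)
        phen = pd.DataFrame({"id": [str(i + 1) for i in range(12)], "y": y})
        res = solve_mme(phen, FixedDesign(intercept=False), eye_K(12), VC)
        np.testing.assert_allclose(
            res.u_hat.to_numpy(), y / (1 + VC.lam), atol=1e-10
        )

    def test_unrecorded_animal_gets_parent_average(self, trio):
        K = build_nrm(trio)
        phen = pd.DataFrame({"id": ["s", "d"], "y": [1.0, -2.0]})
        res = solve_mme(phen, FixedDesign(intercept=False), K, VC)
        assert res.u_hat.loc["o"] == pytest.approx(
            0.5 * (res.u_hat.loc["s"] + res.u_hat.loc["d"]), abs=1e-10
        )

    def test_repeated_records_supported(self):
        phen = pd.DataFrame({"id": ["1", "1", "2"], "y": [1.0, 3.0, 0.5]})
        res = solve_mme(phen, FixedDesign(intercept=False), eye_K(2), VC)
        # two records act like one record of the mean with halved residual var
        lam = VC.lam
        assert res.u_hat.loc["1"] == pytest.approx(2 * 2.0 / (2 + lam))

    def test_pev_bounded_by_genetic_variance(self, std_truth, cg_design):
        res = solve_mme(std_truth.phenotypes, cg_design, std_truth.nrm, VC)
        F = np.diag(std_truth.nrm.matrix) - 1
        assert np.all(np.diag(res.C_uu) <= (1 + F) * VC.sigma2_u + 1e-8)
        assert np.all(np.diag(res.C_uu) >= -1e-10)

    def test_rank_deficient_design_names_columns(self):
        phen = pd.DataFrame(
            {"id": ["1", "2", "3", "4"], "y": [1.0, 2.0, 3.0, 4.0],
             "a": ["x", "x", "z", "z"], "b": ["p", "p", "q", "q"]}
        )
        with pytest.raises(ValueError, match="confounded"):
            solve_mme(phen, FixedDesign(factors=["a", "b"]), eye_K(4), VC)

    def test_unknown_record_id_rejected(self):
        phen = pd.DataFrame({"id": ["99"], "y": [1.0]})
        with pytest.raises(KeyError, match="99"):
            solve_mme(phen, FixedDesign(), eye_K(3), VC)


class TestAccuracyFromPEV:
    def test_extremes(self, fullsib_family):
        K = build_nrm(fullsib_family)
        focal = [f"o{k}" for k in range(10)]
        phen = pd.DataFrame({"id": focal, "y": np.zeros(10)})
        res = solve_mme(phen, FixedDesign(intercept=False), K, VC)
        # no information at all: C_uu = G over the focal block -> acc = 0
        res.C_uu = K.matrix * VC.sigma2_u
        assert accuracy_from_pev(res, K, VC, focal) == pytest.approx(0.0)
        res.C_uu = np.zeros_like(K.matrix)
        assert accuracy_from_pev(res, K, VC, focal) == pytest.approx(1.0)

    def test_single_record_unrelated_accuracy_is_h(self):
        n = 30
        phen = pd.DataFrame({"id": [str(i + 1) for i in range(n)],
                             "y": np.zeros(n)})
        res = solve_mme(phen, FixedDesign(intercept=False), eye_K(n), VC)
        acc = accuracy_from_pev(res, eye_K(n), VC, phen["id"].tolist())
        assert acc == pytest.approx(np.sqrt(VC.h2), abs=1e-10)

    def test_single_individual_rejected(self):
        phen = pd.DataFrame({"id": ["1"], "y": [0.0]})
        res = solve_mme(phen, FixedDesign(intercept=False), eye_K(1), VC)
        with pytest.raises(ValueError, match="undefined"):
            accuracy_from_pev(res, eye_K(1), VC, ["1"])

    def test_matches_empirical_tbv_ebv_correlation(self, std_truth, cg_design):
        # population accuracy from PEV/PEC = corr(u, u_hat) across replicates
        res0 = solve_mme(std_truth.phenotypes, cg_design, std_truth.nrm,
                         std_truth.config.vc)
        focal = list(dict.fromkeys(std_truth.phenotypes["id"]))[:200]
        acc_theory = accuracy_from_pev(res0, std_truth.nrm, std_truth.config.vc, focal)
        rng = np.random.default_rng(11)
        cors = []
        for _ in range(400):
            phen, u = redraw_phenotypes(std_truth, rng)
            res = solve_mme(phen, cg_design, std_truth.nrm, std_truth.config.vc,
                            compute_cov=False)
            idx = {i: k for k, i in enumerate(std_truth.pedigree.ids)}
            fi = [idx[i] for i in focal]
            cors.append(np.corrcoef(u[fi], res.u_hat.loc[focal])[0, 1])
        cors = np.asarray(cors)
        se = cors.std(ddof=1) / np.sqrt(len(cors))
        assert abs(cors.mean() - acc_theory) < 3 * se


class TestPrecorrect:
    def test_zero_beta_returns_y(self):
        phen = pd.DataFrame({"id": ["1", "2"], "y": [1.0, 2.0]})
        res = solve_mme(phen, FixedDesign(intercept=False), eye_K(2), VC)
        np.testing.assert_allclose(precorrect(phen, res), phen["y"])

    def test_level_means_removed_without_genetics(self):
        # lambda -> infinity (negligible genetic variance): GLS -> per-level OLS
        rng = np.random.default_rng(4)
        phen = pd.DataFrame({"id": [str(i + 1) for i in range(40)],
                             "y": rng.normal(2.0, 1.0, 40),
                             "g": ["a"] * 20 + ["b"] * 20})
        vc = VarianceComponents(1e-9, 1.0)
        res = solve_mme(phen, FixedDesign(factors=["g"]), eye_K(40), vc)
        ystar = precorrect(phen, res)
        for g in ("a", "b"):
            assert ystar[phen["g"] == g].mean() == pytest.approx(0.0, abs=1e-5)

    def test_matches_gls_oracle(self, trio):
        # direct V^-1-weighted BLUE on a 6-record, 2-level toy dataset
        K = build_nrm(trio)
        phen = pd.DataFrame({
            "id": ["s", "s", "d", "d", "o", "o"],
            "y": [1.0, 1.4, -0.3, 0.1, 2.2, 1.9],
            "g": ["a", "b", "a", "b", "a", "b"],
        })
        design = FixedDesign(factors=["g"])
        res = solve_mme(phen, design, K, VC)
        Z = np.zeros((6, 3))
        for r, i in enumerate(phen["id"]):
            Z[r, K.ids.index(i)] = 1.0
        V = Z @ K.matrix @ Z.T * VC.sigma2_u + np.eye(6) * VC.sigma2_e
        X = res.design.matrix(phen)
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ phen["y"].to_numpy())
        np.testing.assert_allclose(res.beta_hat.to_numpy(), beta_gls, atol=1e-8)
        np.testing.assert_allclose(
            precorrect(phen, res), phen["y"].to_numpy() - X @ beta_gls, atol=1e-8
        )

    def test_invariant_to_level_ordering(self, trio):
        # renaming levels changes the dropped level but not y*
        K = build_nrm(trio)
        phen = pd.DataFrame({"id": ["s", "d", "o"], "y": [1.0, 2.0, 3.0],
                             "g": ["a", "b", "a"]})
        res1 = solve_mme(phen, FixedDesign(factors=["g"]), K, VC)
        phen2 = phen.assign(g=phen["g"].map({"a": "z", "b": "b"}))
        res2 = solve_mme(phen2, FixedDesign(factors=["g"]), K, VC)
        np.testing.assert_allclose(
            precorrect(phen, res1), precorrect(phen2, res2), atol=1e-10
        )
        np.testing.assert_allclose(
            res1.u_hat.to_numpy(), res2.u_hat.to_numpy(), atol=1e-10
        )

    def test_unseen_level_rejected(self, trio):
        K = build_nrm(trio)
        phen = pd.DataFrame({"id": ["s", "d"], "y": [1.0, 2.0], "g": ["a", "b"]})
        res = solve_mme(phen, FixedDesign(factors=["g"]), K, VC)
        new = pd.DataFrame({"id": ["o"], "y": [0.0], "g": ["c"]})
        with pytest.raises(ValueError, match="'c'"):
            precorrect(new, res)


@pytest.fixture(scope="module")
def small():
    from lrblup import SimulationConfig, simulate_population

    return simulate_population(
        SimulationConfig(n_sires=4, n_dams=16, offspring_per_dam=3,
                         n_groups=4, seed=21)
    )


class TestSamplingIdentities:
    """Monte-Carlo checks of the covariance structure of (u_hat_p, u_hat_w, y*)."""

    def test_var_ystar_equals_v_minus_xcbbx(self, small, cg_design):
        truth = small
        res0 = solve_mme(truth.phenotypes, cg_design, truth.nrm, truth.config.vc)
        X = res0.design.matrix(truth.phenotypes)
        idx = {i: k for k, i in enumerate(truth.pedigree.ids)}
        Z = np.zeros((len(truth.phenotypes), len(truth.pedigree.ids)))
        for r, i in enumerate(truth.phenotypes["id"]):
            Z[r, idx[i]] = 1.0
        V = (Z @ truth.nrm.matrix @ Z.T * truth.config.sigma2_u
             + np.eye(len(X)) * truth.config.sigma2_e)
        theo = np.diag(V - X @ res0.C_bb @ X.T)
        rng = np.random.default_rng(13)
        ys = []
        for _ in range(800):
            phen, _ = redraw_phenotypes(truth, rng)
            res = solve_mme(phen, cg_design, truth.nrm, truth.config.vc,
                            compute_cov=False)
            ys.append(precorrect(phen, res).to_numpy())
        emp = np.var(np.asarray(ys), axis=0, ddof=1)
        # each record's sampling variance matches; compare the average with
        # its Monte-Carlo error (chi-square SE of a variance estimate)
        se = np.sqrt(np.mean((2 * theo**2) / 799)) / np.sqrt(len(theo))
        assert abs(emp.mean() - theo.mean()) < 4 * se

    def test_cov_partial_whole_equals_var_partial(self, small, cg_design):
        truth = small
        rng = np.random.default_rng(17)
        mask = rng.random(len(truth.phenotypes)) < 0.5
        focal = list(dict.fromkeys(truth.phenotypes["id"]))[:8]
        ups, uws = [], []
        for _ in range(1500):
            phen, _ = redraw_phenotypes(truth, rng)
            rp = solve_mme(phen.loc[~mask], cg_design, truth.nrm,
                           truth.config.vc, compute_cov=False)
            rw = solve_mme(phen, cg_design, truth.nrm, truth.config.vc,
                           compute_cov=False)
            ups.append(rp.u_hat.loc[focal].to_numpy())
            uws.append(rw.u_hat.loc[focal].to_numpy())
        ups, uws = np.asarray(ups), np.asarray(uws)
        n = len(ups)
        cov_pw = (ups - ups.mean(0)).T @ (uws - uws.mean(0)) / (n - 1)
        var_p = np.cov(ups.T)
        # elementwise Monte-Carlo SE of a covariance entry
        vp, vw = np.var(ups, axis=0), np.var(uws, axis=0)
        se = np.sqrt((np.outer(vp, vw) + cov_pw**2) / n)
        assert np.all(np.abs(cov_pw - var_p) < 5 * se)


class TestEMREML:
    def test_recovers_simulated_heritability(self, cg_design):
        from lrblup import SimulationConfig, simulate_population

        h2s = []
        for rep in range(16):
            truth = simulate_population(
                SimulationConfig(n_sires=20, n_dams=100, offspring_per_dam=5,
                                 seed=300 + rep)
            )
            r = em_reml(truth.phenotypes, cg_design, truth.nrm,
                        start=VarianceComponents(0.2, 0.8))
            h2s.append(r.h2)
        assert abs(np.mean(h2s) - 0.4) < 0.05

    def test_restart_at_estimate_is_a_fixed_point(self, std_truth, cg_design):
        r1 = em_reml(std_truth.phenotypes, cg_design, std_truth.nrm,
                     start=std_truth.config.vc)
        r2 = em_reml(std_truth.phenotypes, cg_design, std_truth.nrm, start=r1.vc)
        assert r2.n_iter <= 5
        assert r2.vc.sigma2_u == pytest.approx(r1.vc.sigma2_u, rel=1e-3)

    def test_zero_heritability_collapses_to_boundary(self):
        recs = []
        for f in range(10):
            recs += [(f"s{f}", "0", "0"), (f"d{f}", "0", "0")]
            recs += [(f"o{f}_{k}", f"s{f}", f"d{f}") for k in range(30)]
        K = build_nrm(Pedigree.from_records(recs))
        rng = np.random.default_rng(0)
        ids = [f"o{f}_{k}" for f in range(10) for k in range(30)]
        phen = pd.DataFrame({"id": ids, "y": rng.normal(0, 1, len(ids))})
        r = em_reml(phen, FixedDesign(), K, start=VarianceComponents(0.5, 0.5))
        assert r.boundary
        assert r.h2 < 0.01

    def test_nonconvergence_error_carries_trajectory(self, std_truth, cg_design):
        with pytest.raises(RuntimeError, match="trajectory"):
            em_reml(std_truth.phenotypes, cg_design, std_truth.nrm,
                    start=VarianceComponents(0.01, 0.99), max_iter=2)

    def test_more_records_than_parameters_required(self):
        phen = pd.DataFrame({"id": ["1"], "y": [1.0]})
        with pytest.raises(ValueError, match="more records"):
            em_reml(phen, FixedDesign(), eye_K(1), start=VC)
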