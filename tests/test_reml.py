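"""AI-REML: likelihood oracle equivalence, exact score, and estimation."""

import numpy as np
import pytest

import grouprr as gr
from grouprr.reml import REMLOptions, _Worker
from grouprr._sparseops import SparseLDL
from conftest import dense_neg2loglik


@pytest.fixture(scope="module")
def tiny(params, basis):
    """~180 animals, 960 records: small enough for dense-V checks, large
    enough for a regular (interior) REML optimum."""
    ped = gr.simulate_pedigree(3, 4, 4, 5, seed=50)
    gr.compute_inbreeding(ped)
    eff = gr.AnimalEffects(a=gr.simulate_genetic_effects(ped, params.G, 51))
    phen = gr.simulate_pe_and_phenotypes(ped, eff, params, basis, [1, 2], 52)
    design = gr.build_design("individual", phen, basis, ped)
    return dict(ped=ped, phen=phen, design=design, ainv=gr.a_inverse(ped),
                ldA=gr.log_det_A(ped))


class TestLoglik:
    def test_matches_dense_V_route(self, params, tiny):
        mme_val = gr.reml_neg2loglik(params.as_theta(), tiny["design"],
                                     tiny["ainv"], tiny["ldA"])
        dense_val = dense_neg2loglik(tiny["design"], tiny["ped"], params)
        assert mme_val == pytest.approx(dense_val, abs=1e-8)

    def test_matches_dense_V_route_group_model(self, params, basis, tiny):
        import pandas as pd

        ped = tiny["ped"]
        ids = ped.generation_ids(1)
        pens = pd.DataFrame({"pen": np.arange(len(ids)) // 4, "id": ids})
        groups = gr.aggregate_group_records(tiny["phen"], pens)
        design = gr.build_design("group", groups, basis, ped)
        mme_val = gr.reml_neg2loglik(params.as_theta(), design, tiny["ainv"],
                                     tiny["ldA"])
        dense_val = dense_neg2loglik(design, ped, params)
        assert mme_val == pytest.approx(dense_val, abs=1e-8)

    def test_quadratic_scaling_in_y(self, params, tiny):
        """Scaling y by c changes the y'Py part by c^2 (logdets fixed)."""
        theta = params.as_theta()
        d = tiny["design"]
        base = gr.reml_neg2loglik(theta, d, tiny["ainv"], tiny["ldA"])
        from dataclasses import replace

        d2 = replace(d, y=2.0 * d.y)
        scaled = gr.reml_neg2loglik(theta, d2, tiny["ainv"], tiny["ldA"])
        # recover y'Py from the dense oracle to isolate the quadratic part
        from conftest import dense_projection

        Pm, *_ = dense_projection(d, tiny["ped"], params)
        ypy = float(d.y @ Pm @ d.y)
        assert scaled - base == pytest.approx(3.0 * ypy, rel=1e-8)

    def test_out_of_space_theta_rejected(self, tiny):
        theta = gr.TraitParams.default().as_theta()
        theta[6] = -1.0
        with pytest.raises(ValueError):
            gr.reml_neg2loglik(theta, tiny["design"], tiny["ainv"],
                               tiny["ldA"])


class TestScore:
    def test_gradient_matches_finite_differences(self, params, tiny):
        theta = params.as_theta() * 0.9
        g, AI = gr.ai_update(theta, tiny["design"], tiny["ainv"], tiny["ldA"])
        fd = np.empty(7)
        for i in range(7):
            h = 1e-5 * max(abs(theta[i]), 1.0)
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd[i] = (gr.reml_neg2loglik(tp, tiny["design"], tiny["ainv"],
                                        tiny["ldA"])
                     - gr.reml_neg2loglik(tm, tiny["design"], tiny["ainv"],
                                          tiny["ldA"])) / (2 * h)
        np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-6)

    def test_ai_matrix_symmetric_psd(self, params, tiny):
        _, AI = gr.ai_update(params.as_theta(), tiny["design"], tiny["ainv"],
                             tiny["ldA"])
        assert np.abs(AI - AI.T).max() < 1e-10
        assert np.linalg.eigvalsh(AI).min() > -1e-8

    def test_score_mean_zero_at_truth(self, params, basis):
        """E[score] = 0 at the generating parameters (over replicates)."""
        grads = []
        for rep in range(6):
            ped = gr.simulate_pedigree(3, 4, 4, 4, seed=300 + rep)
            gr.compute_inbreeding(ped)
            eff = gr.AnimalEffects(
                a=gr.simulate_genetic_effects(ped, params.G, 400 + rep))
            phen = gr.simulate_pe_and_phenotypes(ped, eff, params, basis,
                                                 [1, 2], 500 + rep)
            design = gr.build_design("individual", phen, basis, ped)
            g, _ = gr.ai_update(params.as_theta(), design,
                                gr.a_inverse(ped), gr.log_det_A(ped))
            grads.append(g)
        grads = np.array(grads)
        se = grads.std(axis=0, ddof=1) / np.sqrt(len(grads))
        assert np.all(np.abs(grads.mean(axis=0)) < 4 * se + 1e-8)


class TestSelectedInverse:
    def test_matches_dense_inverse_on_pattern(self, params, tiny):
        mme = gr.assemble_mme(tiny["design"], tiny["ainv"], params)
        f = SparseLDL(mme.C)
        Ci = np.linalg.inv(mme.C.toarray())
        rr, cc = mme.C.nonzero()
        np.testing.assert_allclose(f.inv_entries(rr, cc), Ci[rr, cc],
                                   atol=1e-9)
        np.testing.assert_allclose(f.inv_diag(), np.diag(Ci), atol=1e-9)

    def test_logdet_and_solve(self, params, tiny):
        mme = gr.assemble_mme(tiny["design"], tiny["ainv"], params)
        f = SparseLDL(mme.C)
        C = mme.C.toarray()
        assert f.logdet == pytest.approx(np.linalg.slogdet(C)[1], abs=1e-9)
        rng = np.random.default_rng(0)
        B = rng.standard_normal((C.shape[0], 3))
        np.testing.assert_allclose(f.solve(B), np.linalg.solve(C, B),
                                   atol=1e-8)

    def test_not_positive_definite_raises(self):
        import scipy.sparse as sp

        M = sp.csc_matrix(np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(np.linalg.LinAlgError):
            SparseLDL(M, perm=np.array([0, 1]))


class TestEstimateVC:
    def test_recovery_small_scale(self, params, basis):
        """Mean estimates over replicates near truth at a miniature scale."""
        thetas = []
        for rep in range(4):
            ped = gr.simulate_pedigree(4, 6, 6, 5, seed=600 + rep)
            gr.compute_inbreeding(ped)
            eff = gr.AnimalEffects(
                a=gr.simulate_genetic_effects(ped, params.G, 700 + rep))
            phen = gr.simulate_pe_and_phenotypes(ped, eff, params, basis,
                                                 [2, 3], 800 + rep)
            design = gr.build_design("individual", phen, basis, ped)
            res = gr.estimate_vc(design, gr.a_inverse(ped),
                                 gr.log_det_A(ped))
            assert res.converged
            thetas.append(res.theta)
        thetas = np.array(thetas)
        mean = thetas.mean(axis=0)
        se = thetas.std(axis=0, ddof=1) / 2
        truth = params.as_theta()
        assert np.all(np.abs(mean - truth) < 4 * se + 0.05 * np.abs(truth))

    def test_warm_start_at_truth_converges_fast(self, params, tiny):
        res = gr.estimate_vc(tiny["design"], tiny["ainv"], tiny["ldA"],
                             theta0=params.as_theta())
        assert res.converged

    def test_monotone_deviance(self, params, tiny):
        res = gr.estimate_vc(tiny["design"], tiny["ainv"], tiny["ldA"])
        lls = [h[1] for h in res.history]
        assert all(b <= a + 1e-7 * abs(a) for a, b in zip(lls, lls[1:]))

    def test_pure_noise_shrinks_to_boundary(self, basis):
        """G = P = 0 truth: residual absorbs the variance, no crash."""
        rng = np.random.default_rng(99)
        ped = gr.simulate_pedigree(3, 4, 4, 4, seed=901)
        gr.compute_inbreeding(ped)
        mask = np.isin(ped.generation, [1, 2])
        import pandas as pd

        ids = ped.ids[mask]
        phen = pd.DataFrame({
            "id": np.repeat(ids, 6),
            "time": np.tile(np.arange(1, 7), len(ids)),
            "value": rng.normal(0.0, 1.0, size=len(ids) * 6),
            "observed": True,
        })
        design = gr.build_design("individual", phen, basis, ped)
        res = gr.estimate_vc(design, gr.a_inverse(ped), gr.log_det_A(ped),
                             options=REMLOptions(max_iter=80))
        assert res.theta[6] == pytest.approx(1.0, rel=0.1)
        assert res.theta[0] < 0.15 and res.theta[3] < 0.15

    def test_nonconvergence_reported_not_raised(self, params, tiny):
        res = gr.estimate_vc(tiny["design"], tiny["ainv"], tiny["ldA"],
                             options=REMLOptions(max_iter=1))
        assert res.converged is False
        assert res.n_iter == 1
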