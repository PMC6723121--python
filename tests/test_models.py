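"""Group-record aggregation, design matrices and the mixed-model equations."""

import numpy as np
import pandas as pd
import pytest

import grouprr as gr
from grouprr.evaluation import solve_blup
from conftest import dense_blup


def _phen(values):
    """Phenotype table for animals 1..n, one time point per column."""
    n, T = values.shape
    return pd.DataFrame({
        "id": np.repeat(np.arange(1, n + 1), T),
        "time": np.tile(np.arange(1, T + 1), n),
        "value": values.ravel(),
        "observed": True,
    })


class TestAggregateGroupRecords:
    def test_sums_and_counts(self):
        phen = _phen(np.array([[10.0], [12.0], [14.0]]))
        pens = pd.DataFrame({"pen": [0, 0, 0], "id": [1, 2, 3]})
        out = gr.aggregate_group_records(phen, pens)
        assert out.loc[0, "y_star"] == 36.0
        assert out.loc[0, "n"] == 3
        assert out.loc[0, "members"] == (1, 2, 3)

    def test_dropped_member_excluded(self):
        phen = _phen(np.array([[10.0, 10.0], [12.0, 12.0], [14.0, 14.0]]))
        plan = pd.DataFrame({"id": [3], "drop_time": [2], "strategy": "r"})
        phen = gr.apply_dropout(phen, plan)
        pens = pd.DataFrame({"pen": [0] * 3, "id": [1, 2, 3]})
        out = gr.aggregate_group_records(phen, pens).set_index("time")
        assert out.loc[1, "y_star"] == 36.0 and out.loc[1, "n"] == 3
        assert out.loc[2, "y_star"] == 22.0 and out.loc[2, "n"] == 2

    def test_fully_dropped_cell_omitted(self):
        phen = _phen(np.array([[1.0, 1.0]]))
        plan = pd.DataFrame({"id": [1], "drop_time": [2], "strategy": "r"})
        phen = gr.apply_dropout(phen, plan)
        pens = pd.DataFrame({"pen": [0], "id": [1]})
        out = gr.aggregate_group_records(phen, pens)
        assert list(out["time"]) == [1]

    def test_member_without_phenotype_rejected(self):
        phen = _phen(np.array([[1.0]]))
        pens = pd.DataFrame({"pen": [0, 0], "id": [1, 2]})
        with pytest.raises(ValueError):
            gr.aggregate_group_records(phen, pens)


class TestBuildDesign:
    def test_group_row_sums_member_covariates(self, basis):
        ped = gr.simulate_pedigree(2, 1, 1, 3, seed=1)
        phen = _phen(np.zeros((5, 6)) + 1.0)
        pens = pd.DataFrame({"pen": [0, 0, 0, 1, 1], "id": [1, 2, 3, 4, 5]})
        groups = gr.aggregate_group_records(phen, pens)
        design = gr.build_design("group", groups, basis, ped)
        # row of pen 0 at t=1 has phi(1) in each of the 3 members' columns
        row0 = design.Za[0].toarray().ravel()
        for a in (1, 2, 3):
            np.testing.assert_allclose(row0[2 * (a - 1):2 * a], basis[0])
        assert design.r0[0] == 3.0

    def test_group_residual_weight_is_group_size(self, basis):
        ped = gr.simulate_pedigree(2, 2, 3, 2, seed=2)
        ids = ped.generation_ids(1)
        phen = _phen(np.random.default_rng(0).normal(size=(ped.n, 6)))
        pens = pd.DataFrame({"pen": 0, "id": ids})
        groups = gr.aggregate_group_records(phen[phen.id.isin(ids)], pens)
        design = gr.build_design("group", groups, basis, ped)
        assert np.all(design.r0 == len(ids))

    def test_sum_consistency_of_linear_predictor(self, params, basis,
                                                 small_dataset):
        """Group-model predictor at the true effects = sum of member
        individual predictors (zero fixed effects in simulation)."""
        ped = small_dataset["ped"]
        eff = small_dataset["effects"]
        phen = small_dataset["phen"]
        ids = ped.generation_ids(2)
        pens = pd.DataFrame({"pen": np.arange(len(ids)) // 3, "id": ids})
        groups = gr.aggregate_group_records(phen, pens)
        gd = gr.build_design("group", groups, basis, ped)
        true_a = eff.a.ravel()
        true_pe = eff.pe[gd.pe_ids - 1].ravel()
        pred_group = gd.Za @ true_a + gd.Zp @ true_pe
        id_ = gr.build_design("individual", phen, basis, ped)
        pred_ind = id_.Za @ true_a + id_.Zp @ eff.pe[id_.pe_ids - 1].ravel()
        ind = pd.DataFrame({"id": phen["id"], "time": phen["time"],
                            "pred": pred_ind}).merge(pens, on="id")
        summed = ind.groupby(["pen", "time"])["pred"].sum().to_numpy()
        np.testing.assert_allclose(pred_group, summed, atol=1e-10)

    def test_unobserved_time_rejected(self, basis):
        ped = gr.simulate_pedigree(2, 1, 1, 2, seed=3)
        phen = _phen(np.ones((4, 8)))
        with pytest.raises(ValueError):
            gr.build_design("individual", phen, basis, ped)


class TestAssembleMME:
    def test_single_founder_ridge_solution(self, basis):
        # one founder, one record at t=1, no PE/fixed contribution in the
        # limit of huge PE variance removed by comparing to closed form
        ped = gr.Pedigree(sire=np.array([0]), dam=np.array([0]),
                          sex=np.array([1]), generation=np.array([0]),
                          litter=np.array([0]))
        y = 3.7
        phen = _phen(np.array([[y]]))
        L1 = basis[:1]
        design = gr.build_design("individual", phen, L1, ped)
        params = gr.TraitParams.default()
        # strip fixed and PE by editing the design to the additive part only
        import scipy.sparse as sp

        design.X = sp.csr_matrix((1, 0))
        design.Zp = sp.csr_matrix((1, 0))
        design.pe_ids = np.array([], dtype=int)
        mme = gr.assemble_mme(design, gr.a_inverse(ped), params)
        phi = basis[0]
        se2 = params.sigma_e2
        expected = np.linalg.solve(
            np.outer(phi, phi) / se2 + np.linalg.inv(params.G),
            phi * y / se2)
        np.testing.assert_allclose(
            np.linalg.solve(mme.C.toarray(), mme.rhs), expected, atol=1e-10)

    def test_blup_matches_dense_gls(self, params, small_dataset):
        L = gr.default_basis()
        design = small_dataset["design"]
        mme = gr.assemble_mme(design, small_dataset["ainv"], params)
        ebv = solve_blup(mme, L)
        beta, u_a, u_p = dense_blup(design, small_dataset["ped"], params)
        np.testing.assert_allclose(ebv.fixed, beta, atol=1e-6)
        np.testing.assert_allclose(ebv.a_hat.ravel(), u_a, atol=1e-6)
        np.testing.assert_allclose(ebv.pe_hat.ravel(), u_p, atol=1e-6)

    def test_singular_G_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            bad = gr.TraitParams.default()
            object.__setattr__(bad, "G", np.ones((2, 2)))
            gr.assemble_mme(small_dataset["design"], small_dataset["ainv"],
                            bad)

    def test_group_size_one_equals_individual(self, params, basis,
                                              small_dataset):
        """Singleton pens give the individual-model MME exactly."""
        ped = small_dataset["ped"]
        phen = small_dataset["phen"]
        pens = pd.DataFrame({"pen": np.arange((phen["id"].nunique())),
                             "id": np.sort(phen["id"].unique())})
        groups = gr.aggregate_group_records(phen, pens)
        gd = gr.build_design("group", groups, basis, ped)
        idd = gr.build_design("individual", phen, basis, ped)
        ainv = small_dataset["ainv"]
        mg = gr.assemble_mme(gd, ainv, params)
        mi = gr.assemble_mme(idd, ainv, params)
        assert gd.n_fixed == idd.n_fixed == 2
        assert np.abs((mg.C - mi.C)).max() < 1e-10
        np.testing.assert_allclose(mg.rhs, mi.rhs, atol=1e-10)
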