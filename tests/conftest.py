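"""Shared fixtures: small simulated datasets and dense-matrix oracles.

The dense oracles recompute REML log-likelihoods and BLUP solutions from
the explicit phenotypic covariance matrix V = Z Sigma Z' + R, independent
of the sparse mixed-model-equation path they are used to check.
"""

import numpy as np
import pytest

import grouprr as gr


@pytest.fixture(scope="session")
def params():
    return gr.TraitParams.default()


@pytest.fixture(scope="session")
def basis():
    return gr.default_basis()


@pytest.fixture(scope="session")
def small_dataset(params, basis):
    """~36 animals, 1 phenotyped generation; small enough for dense oracles."""
    ped = gr.simulate_pedigree(3, 2, 2, 3, seed=3)
    gr.compute_inbreeding(ped)
    a = gr.simulate_genetic_effects(ped, params.G, seed=4)
    effects = gr.AnimalEffects(a=a)
    phen = gr.simulate_pe_and_phenotypes(ped, effects, params, basis,
                                         phenotyped_generations=[2], seed=5)
    design = gr.build_design("individual", phen, basis, ped)
    return dict(ped=ped, effects=effects, phen=phen, design=design,
                ainv=gr.a_inverse(ped), ldA=gr.log_det_A(ped))


def dense_V(design, ped, params):
    A = gr.tabular_A(ped)
    Za = design.Za.toarray()
    Zp = design.Zp.toarray()
    n_pe = len(design.pe_ids)
    return (Za @ np.kron(A, params.G) @ Za.T
            + Zp @ np.kron(np.eye(n_pe), params.P) @ Zp.T
            + np.diag(design.r0) * params.sigma_e2)


def dense_projection(design, ped, params):
    """P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1 (REML projector)."""
    V = dense_V(design, ped, params)
    Vi = np.linalg.inv(V)
    X = design.X.toarray()
    XtViX = X.T @ Vi @ X
    return Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi), V, Vi, XtViX


def dense_neg2loglik(design, ped, params):
    Pm, V, Vi, XtViX = dense_projection(design, ped, params)
    y = design.y
    return (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1]
            + float(y @ Pm @ y))


def dense_blup(design, ped, params):
    """GLS fixed effects and BLUP random effects from the dense V route."""
    Pm, V, Vi, XtViX = dense_projection(design, ped, params)
    X = design.X.toarray()
    y = design.y
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    A = gr.tabular_A(ped)
    Za = design.Za.toarray()
    Zp = design.Zp.toarray()
    n_pe = len(design.pe_ids)
    u_a = np.kron(A, params.G) @ Za.T @ Vi @ resid
    u_p = np.kron(np.eye(n_pe), params.P) @ Zp.T @ Vi @ resid
    return beta, u_a, u_p
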