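"""AI-REML estimation of the random-regression variance components.

The parameter vector is theta = (G11, G12, G22, P11, P12, P22, sigma_e2).
Writing V = Z_a (A (x) G) Z_a' + Z_pe (I (x) P) Z_pe' + R with
R = diag(r0) sigma_e2, the REML deviance is evaluated through the
mixed-model equations:

    -2 logL_R = log|C| + log|R| + log|A (x) G| + log|I (x) P| + y' P y,

where C is the MME coefficient matrix and y'Py = y'R^-1 y - rhs' shat.
The score uses exact traces obtained from the selected inverse of C on its
own sparsity pattern (Takahashi recurrences); the average-information
matrix AI_ij = y' P V_i P V_j P y needs only solves against the factorized
C.  Updates are Newton steps with the AI matrix, with step halving to keep
the deviance monotone; a proposal outside the parameter space (non-PD G or
P, or sigma_e2 <= 0) is replaced by an EM-REML step for that iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._sparseops import SparseLDL
from .models import (Design, assemble_mme, mme_elimination_order,
                     sigma_inv_augmentation)
from .population import TraitParams

__all__ = ["REMLResult", "REMLOptions", "reml_neg2loglik", "ai_update",
           "em_update", "estimate_vc", "default_start"]

_EIG_FLOOR = 1e-8

# symmetric basis matrices for d/dtheta of a packed 2x2 covariance
_E = [np.array([[1.0, 0.0], [0.0, 0.0]]),
      np.array([[0.0, 1.0], [1.0, 0.0]]),
      np.array([[0.0, 0.0], [0.0, 1.0]])]


def theta_in_space(theta) -> bool:
    t = np.asarray(theta, dtype=float)
    G = np.array([[t[0], t[1]], [t[1], t[2]]])
    P = np.array([[t[3], t[4]], [t[4], t[5]]])
    return (
        np.linalg.eigvalsh(G).min() > _EIG_FLOOR
        and np.linalg.eigvalsh(P).min() > _EIG_FLOOR
        and t[6] > _EIG_FLOOR
    )


@dataclass
class REMLOptions:
    tol_param: float = 1e-8
    tol_grad: float = 1e-6
    tol_dev: float = 1e-6     # relative deviance stall (boundary detection)
    max_iter: int = 200
    max_halving: int = 12
    verbose: bool = False


@dataclass
class REMLResult:
    theta: np.ndarray
    neg2loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    ai_matrix: np.ndarray
    used_em: int = 0
    at_boundary: bool = False
    history: list = field(default_factory=list)

    @property
    def params(self) -> TraitParams:
        return TraitParams.from_theta(self.theta)


@dataclass
class _State:
    """Factorization and solutions of the MME at one theta."""
    theta: np.ndarray
    factor: SparseLDL
    sol: np.ndarray
    neg2ll: float
    resid: np.ndarray       # y - W shat
    rinv: np.ndarray        # 1 / (r0 sigma_e2)


def _guard_theta(theta) -> np.ndarray:
    """Nudge exactly-zero covariances off zero (~1e-10 relative).

    scipy's sparse addition prunes explicit zeros, so G12 = 0 or P12 = 0
    would silently shrink the MME sparsity pattern and invalidate the
    selected-inverse trace lookups; the nudge is far below every tolerance
    used anywhere in the package.
    """
    t = np.asarray(theta, dtype=float).copy()
    if t[1] == 0.0:
        t[1] = 1e-10 * np.sqrt(abs(t[0] * t[2]) + 1e-300)
    if t[4] == 0.0:
        t[4] = 1e-10 * np.sqrt(abs(t[3] * t[5]) + 1e-300)
    return t


def _factor_state(theta, design: Design, a_inv, log_det_a, perm=None,
                  symbolic=None) -> _State:
    theta = _guard_theta(theta)
    params = TraitParams.from_theta(theta)
    mme = assemble_mme(design, a_inv, params)
    factor = SparseLDL(mme.C, perm=perm, symbolic=symbolic)
    sol = factor.solve(mme.rhs)
    W = design.W
    resid = design.y - W @ sol
    rinv = 1.0 / (design.r0 * params.sigma_e2)
    ypy = float(design.y @ (design.y * rinv) - mme.rhs @ sol)
    n_ped = design.n_ped
    n_pe = len(design.pe_ids)
    logdetR = float(np.sum(np.log(design.r0 * params.sigma_e2)))
    logdetSig = (
        2.0 * log_det_a
        + n_ped * np.log(np.linalg.det(params.G))
        + n_pe * np.log(np.linalg.det(params.P))
    )
    neg2ll = factor.logdet + logdetR + logdetSig + ypy
    return _State(np.asarray(theta, float), factor, sol, neg2ll, resid, rinv)


def reml_neg2loglik(theta, design: Design, a_inv, log_det_a: float) -> float:
    """-2 restricted log-likelihood (up to the usual constant)."""
    if not theta_in_space(theta):
        raise ValueError("theta outside the parameter space")
    return _factor_state(theta, design, a_inv, log_det_a).neg2ll


def _block_entry_indices(design: Design, a_inv):
    """Equation-index arrays for the C^-1 entries entering the traces."""
    nf = design.n_fixed
    k = design.n_coef
    coo = sp.coo_matrix(sp.triu(a_inv))
    ai, aj, av = coo.row, coo.col, coo.data
    # 2x2 block between animals i and j, for every stored entry of A^-1
    rr, cc = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    add_rows = (nf + k * ai[:, None, None] + rr[None]).ravel()
    add_cols = (nf + k * aj[:, None, None] + cc[None]).ravel()
    off_pe = nf + k * design.n_ped
    n_pe = len(design.pe_ids)
    pe_rows = (off_pe + k * np.arange(n_pe)[:, None, None] + rr[None]).ravel()
    pe_cols = (off_pe + k * np.arange(n_pe)[:, None, None] + cc[None]).ravel()
    return (ai, aj, av), (add_rows, add_cols), (pe_rows, pe_cols)


class _Worker:
    """Carries the per-dataset constants across REML iterations."""

    def __init__(self, design: Design, a_inv, log_det_a: float):
        self.design = design
        self.a_inv = sp.csc_matrix(a_inv)
        self.log_det_a = float(log_det_a)
        self.perm = mme_elimination_order(design)
        self._symbolic = None
        self._Q = None
        self._qy = None
        (self._aentries, self._aidx, self._pidx) = _block_entry_indices(
            design, self.a_inv
        )
        self.W = design.W
        self.Wt = self.W.T.tocsr()

    def state(self, theta) -> _State:
        """Factorize the MME at theta with a pattern frozen across iterations.

        W'R^-1 W is W'R0^-1 W / sigma_e2, so its sparse pattern (computed
        once) never changes; rebuilding it per iteration would let float
        cancellations in the near-orthogonal Legendre cross-products flip
        entries in and out of the stored pattern between iterations.
        """
        theta = _guard_theta(theta)
        params = TraitParams.from_theta(theta)
        design = self.design
        if self._Q is None:
            rinv0 = 1.0 / design.r0
            WtR0 = self.W.T.multiply(rinv0).tocsc()
            self._Q = (WtR0 @ self.W).tocsc()
            self._qy = np.asarray(WtR0 @ design.y).ravel()
        se2 = params.sigma_e2
        C = (self._Q * (1.0 / se2)
             + sigma_inv_augmentation(design, self.a_inv, params)).tocsc()
        C.sort_indices()
        rhs = self._qy / se2
        factor = SparseLDL(C, perm=self.perm, symbolic=self._symbolic)
        if self._symbolic is None:
            self._symbolic = factor.symbolic
        sol = factor.solve(rhs)
        resid = design.y - self.W @ sol
        rinv = 1.0 / (design.r0 * se2)
        ypy = float(design.y @ (design.y * rinv) - rhs @ sol)
        logdetR = float(np.sum(np.log(design.r0 * se2)))
        logdetSig = (
            2.0 * self.log_det_a
            + design.n_ped * np.log(np.linalg.det(params.G))
            + len(design.pe_ids) * np.log(np.linalg.det(params.P))
        )
        neg2ll = factor.logdet + logdetR + logdetSig + ypy
        return _State(theta, factor, sol, neg2ll, resid, rinv)

    # -- pieces shared by the score, the AI matrix and the EM update -------

    def _solution_blocks(self, st: _State):
        nf = self.design.n_fixed
        k = self.design.n_coef
        n_ped = self.design.n_ped
        n_pe = len(self.design.pe_ids)
        U = st.sol[nf:nf + k * n_ped].reshape(n_ped, k)
        Ppe = st.sol[nf + k * n_ped:].reshape(n_pe, k)
        return U, Ppe

    def _inv_block_sums(self, st: _State, B_add, B_pe):
        """tr(C^aa (A^-1 (x) B_add)) and tr(C^pp (I (x) B_pe)) for each B."""
        (ai, aj, av) = self._aentries
        add_vals = st.factor.inv_entries(*self._aidx)
        pe_vals = st.factor.inv_entries(*self._pidx)
        k = self.design.n_coef
        nA = len(ai)
        add_blocks = add_vals.reshape(nA, k, k)
        pe_blocks = pe_vals.reshape(len(self.design.pe_ids), k, k)
        off_diag = (ai != aj)
        w = np.where(off_diag, 2.0, 1.0) * av  # symmetric double-count
        tr_add = [float(np.einsum("n,nkl,lk->", w, add_blocks, B)) for B in B_add]
        tr_pe = [float(np.einsum("nkl,lk->", pe_blocks, B)) for B in B_pe]
        return tr_add, tr_pe, add_blocks, pe_blocks, w

    def _apply_P(self, st: _State, V: np.ndarray) -> np.ndarray:
        """P v = R^-1 (v - W C^-1 W' R^-1 v) for columns of V."""
        Tv = V * st.rinv[:, None]
        S = st.factor.solve(np.asarray(self.Wt @ Tv))
        return Tv - (self.W @ S) * st.rinv[:, None]

    def score_and_ai(self, st: _State):
        """Gradient of -2logL and the average-information matrix."""
        params = TraitParams.from_theta(st.theta)
        Ginv = np.linalg.inv(params.G)
        Pinv = np.linalg.inv(params.P)
        se2 = params.sigma_e2
        n_ped = self.design.n_ped
        n_pe = len(self.design.pe_ids)
        nrec = self.design.n_records
        neq = st.factor.n

        B_add = [Ginv @ E @ Ginv for E in _E]
        B_pe = [Pinv @ E @ Pinv for E in _E]
        tr_add, tr_pe, *_ = self._inv_block_sums(st, B_add + [Ginv],
                                                 B_pe + [Pinv])
        trCS = tr_add[3] + tr_pe[3]

        U, Ppe = self._solution_blocks(st)
        w0 = st.resid * st.rinv  # P y
        # V_i (P y) for each component
        F = np.empty((nrec, 7))
        for m, B in enumerate(B_add[:3]):
            F[:, m] = self.design.Za @ (U @ (_E[m] @ Ginv).T).ravel()
        for m, B in enumerate(B_pe[:3]):
            F[:, 3 + m] = self.design.Zp @ (Ppe @ (_E[m] @ Pinv).T).ravel()
        F[:, 6] = st.resid / se2  # R0 P y

        quads = F.T @ w0  # y' P V_i P y
        traces = np.empty(7)
        for m in range(3):
            traces[m] = n_ped * np.trace(_E[m] @ Ginv) - tr_add[m]
            traces[3 + m] = n_pe * np.trace(_E[m] @ Pinv) - tr_pe[m]
        traces[6] = (nrec - neq + trCS) / se2

        grad = traces - quads
        PF = self._apply_P(st, F)
        AI = F.T @ PF
        AI = 0.5 * (AI + AI.T)
        return grad, AI

    def em_step(self, st: _State) -> np.ndarray:
        """One EM-REML update of all components (always in-space)."""
        params = TraitParams.from_theta(st.theta)
        Ginv = np.linalg.inv(params.G)
        Pinv = np.linalg.inv(params.P)
        se2 = params.sigma_e2
        n_ped = self.design.n_ped
        n_pe = len(self.design.pe_ids)
        nrec = self.design.n_records
        neq = st.factor.n

        _, _, add_blocks, pe_blocks, w = self._inv_block_sums(st, [], [])
        U, Ppe = self._solution_blocks(st)
        S = self.a_inv @ U
        quad_G = U.T @ S
        trace_G = np.einsum("n,nkl->kl", w, add_blocks)
        G_new = (quad_G + 0.5 * (trace_G + trace_G.T)) / n_ped

        quad_P = Ppe.T @ Ppe
        trace_P = pe_blocks.sum(axis=0)
        P_new = (quad_P + 0.5 * (trace_P + trace_P.T)) / n_pe

        tr_add_Ginv = float(np.einsum("n,nkl,lk->", w, add_blocks, Ginv))
        tr_pe_Pinv = float(np.einsum("nkl,lk->", pe_blocks, Pinv))
        trCS = tr_add_Ginv + tr_pe_Pinv
        quad_e = float(st.resid @ (st.resid / self.design.r0)) / se2**2
        trace_e = (nrec - neq + trCS) / se2
        se2_new = se2 + se2**2 / nrec * (quad_e - trace_e)

        return np.array([G_new[0, 0], G_new[0, 1], G_new[1, 1],
                         P_new[0, 0], P_new[0, 1], P_new[1, 1], se2_new])


def ai_update(theta, design: Design, a_inv, log_det_a: float):
    """Gradient of -2logL_R and the AI matrix at theta (one-shot API)."""
    if not theta_in_space(theta):
        raise ValueError("theta outside the parameter space")
    worker = _Worker(design, a_inv, log_det_a)
    st = worker.state(np.asarray(theta, float))
    return worker.score_and_ai(st)


def em_update(theta, design: Design, a_inv, log_det_a: float) -> np.ndarray:
    worker = _Worker(design, a_inv, log_det_a)
    st = worker.state(np.asarray(theta, float))
    return worker.em_step(st)


def default_start(design: Design, T: int = 6) -> np.ndarray:
    """Heuristic starting values from the raw phenotypic variance.

    For group records the per-individual phenotypic variance is
    approximated by var(y*/sqrt(n)), exact for unrelated pen mates.
    """
    vp = float(np.var(design.y / np.sqrt(design.r0), ddof=1))
    return np.array([vp / 4, 0.0, vp / 4 / T, vp / 4, 0.0, vp / 4 / T,
                     vp / 2])


def estimate_vc(design: Design, a_inv, log_det_a: float, theta0=None,
                options: REMLOptions | None = None) -> REMLResult:
    """AI-REML with step halving and EM fallback (see module docstring)."""
    opts = options or REMLOptions()
    theta = np.asarray(
        default_start(design) if theta0 is None else theta0, dtype=float
    ).copy()
    if not theta_in_space(theta):
        raise ValueError("starting theta outside the parameter space")

    worker = _Worker(design, sp.csc_matrix(a_inv), log_det_a)
    st = worker.state(theta)
    used_em = 0
    history = []
    grad = np.full(7, np.inf)
    AI = np.eye(7)
    converged = False
    at_boundary = False
    small_steps = 0
    em_stall = 0
    it = 0
    for it in range(1, opts.max_iter + 1):
        grad, AI = worker.score_and_ai(st)
        grad_norm = float(np.linalg.norm(grad))
        history.append((it, st.neg2ll, grad_norm))
        if opts.verbose:
            print(f"iter {it:3d}  -2logL {st.neg2ll:.6f}  |g| {grad_norm:.3e}")

        # Newton direction on -2logL; ridge the AI matrix if near-singular
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(7) * np.trace(AI),
                                    -grad)
        except np.linalg.LinAlgError:
            delta = -grad / max(np.trace(AI), 1.0)

        step = 1.0
        new_state = None
        em_used_here = False
        for _ in range(opts.max_halving + 1):
            cand = theta + step * delta
            if not theta_in_space(cand):
                step *= 0.5
                continue
            trial = worker.state(cand)
            if trial.neg2ll <= st.neg2ll + 1e-10 * abs(st.neg2ll):
                new_state = trial
                break
            step *= 0.5
        if new_state is None:
            # AI step failed entirely: EM fallback
            cand = worker.em_step(st)
            if not theta_in_space(cand):
                cand = np.maximum(cand, _EIG_FLOOR * 10)
                cand[1] = np.clip(cand[1], -np.sqrt(cand[0] * cand[2]) * 0.99,
                                  np.sqrt(cand[0] * cand[2]) * 0.99)
                cand[4] = np.clip(cand[4], -np.sqrt(cand[3] * cand[5]) * 0.99,
                                  np.sqrt(cand[3] * cand[5]) * 0.99)
            new_state = worker.state(cand)
            used_em += 1
            em_used_here = True

        rel_change = float(np.max(np.abs(new_state.theta - theta)
                                  / (np.abs(theta) + 1.0)))
        dev_gain = st.neg2ll - new_state.neg2ll
        theta = new_state.theta
        st = new_state
        # an optimum on the PD boundary of G or P makes every AI proposal
        # leave the space; the EM fallback then creeps with vanishing
        # deviance gains -- declare boundary convergence after three such
        # iterations instead of crawling to the iteration cap
        if em_used_here and dev_gain < opts.tol_dev * (1 + abs(st.neg2ll)):
            em_stall += 1
            if em_stall >= 3:
                converged = True
                at_boundary = True
                break
        else:
            em_stall = 0
        if rel_change < opts.tol_param:
            if grad_norm < opts.tol_grad and not em_used_here:
                converged = True
                break
            # parameter change has vanished but the gradient has not: the
            # optimum sits on (or next to) the PD boundary of G or P, where
            # the score does not vanish; declare boundary convergence after
            # three consecutive dead iterations
            small_steps += 1
            if small_steps >= 3:
                converged = True
                at_boundary = True
                break
        else:
            small_steps = 0

    grad, AI = worker.score_and_ai(st)
    grad_norm = float(np.linalg.norm(grad))
    if not converged and grad_norm < opts.tol_grad:
        converged = True
    return REMLResult(
        theta=theta,
        neg2loglik=st.neg2ll,
        converged=converged,
        n_iter=it,
        grad_norm=grad_norm,
        ai_matrix=AI,
        used_em=used_em,
        at_boundary=at_boundary,
        history=history,
    )
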