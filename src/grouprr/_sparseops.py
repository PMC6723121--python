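"""Sparse symmetric LDL' factorization with selected (Takahashi) inverse.

The REML machinery needs, per iteration: log|C| of the mixed-model
coefficient matrix, solves against it, and the elements of C^-1 on the
sparsity pattern of C (for exact trace terms in the score).  scipy ships
an LU but no symmetric factorization and no selected inverse, so this
module provides an up-looking sparse LDL' (after Davis's LDL algorithm)
and the Takahashi recurrences on the filled pattern, both numba-compiled.
A fill-reducing symmetric ordering is borrowed from SuperLU's
``MMD_AT_PLUS_A`` column permutation.

All quantities are exact (no Monte-Carlo trace estimation).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit

__all__ = ["SparseLDL"]


@njit(cache=False)
def _ldl_symbolic(n, Ap, Ai):
    parent = np.full(n, -1, dtype=np.int64)
    flag = np.empty(n, dtype=np.int64)
    Lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        parent[k] = -1
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i < k and flag[i] != k:
                if parent[i] == -1:
                    parent[i] = k
                Lnz[i] += 1
                flag[i] = k
                i = parent[i]
    Lp = np.zeros(n + 1, dtype=np.int64)
    for k in range(n):
        Lp[k + 1] = Lp[k] + Lnz[k]
    return parent, Lp


@njit(cache=False)
def _ldl_numeric(n, Ap, Ai, Ax, parent, Lp):
    Li = np.empty(Lp[n], dtype=np.int64)
    Lx = np.empty(Lp[n])
    D = np.empty(n)
    Y = np.zeros(n)
    pattern = np.empty(n, dtype=np.int64)
    stack = np.empty(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    Lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        Y[k] = 0.0
        top = n
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            Y[i] += Ax[p]
            ln = 0
            while flag[i] != k:
                pattern[ln] = i
                ln += 1
                flag[i] = k
                i = parent[i]
            while ln > 0:
                ln -= 1
                top -= 1
                stack[top] = pattern[ln]
        D[k] = Y[k]
        Y[k] = 0.0
        while top < n:
            i = stack[top]
            yi = Y[i]
            Y[i] = 0.0
            for p in range(Lp[i], Lp[i] + Lnz[i]):
                Y[Li[p]] -= Lx[p] * yi
            lki = yi / D[i]
            D[k] -= lki * yi
            Li[Lp[i] + Lnz[i]] = k
            Lx[Lp[i] + Lnz[i]] = lki
            Lnz[i] += 1
            top += 1
        if D[k] <= 0.0:
            # not positive definite
            return Li, Lx, D, k
    return Li, Lx, D, -1


@njit(cache=False)
def _ldl_solve(n, Lp, Li, Lx, D, B):
    """Solve L D L' X = B in place for (possibly multi-column) B."""
    ncol = B.shape[1]
    for c in range(ncol):
        for j in range(n):
            xj = B[j, c]
            if xj != 0.0:
                for p in range(Lp[j], Lp[j + 1]):
                    B[Li[p], c] -= Lx[p] * xj
        for j in range(n):
            B[j, c] /= D[j]
        for j in range(n - 1, -1, -1):
            s = B[j, c]
            for p in range(Lp[j], Lp[j + 1]):
                s -= Lx[p] * B[Li[p], c]
            B[j, c] = s
    return B


@njit(cache=False)
def _takahashi_full(n, Lp, Li, Lx, D, Zp, Zi, mirror):
    """Takahashi recurrences on the symmetrized filled pattern.

    Z is stored on the full (both triangles + diagonal) pattern of L.
    Columns are processed right to left; a strict-lower entry Z_ij is
    Z_ij = -sum_k L_kj Z_ki, accumulated by walking the already-complete
    column i of Z against a dense scatter of column j of L, and every
    lower entry is mirrored into its transposed position immediately so
    later (smaller) columns see complete columns.
    """
    Zx = np.zeros(Zp[n])
    z = np.zeros(n)
    for j in range(n - 1, -1, -1):
        l0, l1 = Lp[j], Lp[j + 1]
        for p in range(l0, l1):
            z[Li[p]] = Lx[p]
        z0, z1 = Zp[j], Zp[j + 1]
        diag_pos = -1
        for p in range(z1 - 1, z0 - 1, -1):
            i = Zi[p]
            if i < j:
                continue
            if i == j:
                diag_pos = p
                continue
            s = 0.0
            for q in range(Zp[i], Zp[i + 1]):
                s += z[Zi[q]] * Zx[q]
            Zx[p] = -s
            Zx[mirror[p]] = -s
        s = 1.0 / D[j]
        for p in range(z0, z1):
            if Zi[p] > j:
                s -= z[Zi[p]] * Zx[p]
        Zx[diag_pos] = s
        for p in range(l0, l1):
            z[Li[p]] = 0.0
    return Zx


@njit(cache=False)
def _gather_entries(Zp, Zi, Zx, rows, cols):
    out = np.empty(len(rows))
    for t in range(len(rows)):
        r, c = rows[t], cols[t]
        lo, hi = Zp[c], Zp[c + 1]
        v = 0.0
        while lo < hi:
            mid = (lo + hi) // 2
            if Zi[mid] < r:
                lo = mid + 1
            elif Zi[mid] > r:
                hi = mid
            else:
                v = Zx[mid]
                break
        out[t] = v
    return out


def _mmd_ordering(C: sp.csc_matrix) -> np.ndarray:
    """Fill-reducing symmetric ordering from SuperLU (MMD on A'+A)."""
    from scipy.sparse.linalg import splu

    # shift to make the matrix comfortably factorizable for ordering only
    n = C.shape[0]
    M = (C + sp.identity(n, format="csc") * (abs(C).sum() / n)).tocsc()
    lu = splu(M, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True))
    return lu.perm_c.astype(np.int64)


class _Symbolic:
    """Reusable symbolic analysis for matrices sharing one sparsity pattern."""

    __slots__ = ("n", "nnz", "parent", "Lp", "Zp", "Zi", "mirror")

    def __init__(self, n, nnz, parent, Lp):
        self.n, self.nnz, self.parent, self.Lp = n, nnz, parent, Lp
        self.Zp = self.Zi = self.mirror = None


class SparseLDL:
    """LDL' factorization of a sparse symmetric positive-definite matrix.

    Parameters
    ----------
    C : scipy sparse matrix (symmetric, both triangles stored)
    perm : optional precomputed fill-reducing permutation; pass the ``perm``
        attribute of a previous factorization with the same pattern to skip
        the ordering step.
    symbolic : optional ``symbolic`` attribute of a previous factorization
        with the identical pattern and permutation (validated by size and
        nonzero count), reused to skip the symbolic analysis.
    """

    def __init__(self, C, perm=None, symbolic=None):
        C = sp.csc_matrix(C)
        self.n = C.shape[0]
        if perm is None:
            perm = _mmd_ordering(C)
        self.perm = np.asarray(perm, dtype=np.int64)
        self.iperm = np.empty(self.n, dtype=np.int64)
        self.iperm[self.perm] = np.arange(self.n)
        Cp = C[self.perm, :][:, self.perm].tocsc()
        Cp.sort_indices()
        self._Ap = Cp.indptr.astype(np.int64)
        self._Ai = Cp.indices.astype(np.int64)
        if symbolic is not None and (symbolic.n != self.n
                                     or symbolic.nnz != Cp.nnz):
            symbolic = None  # pattern changed; redo the analysis
        if symbolic is None:
            parent, Lp = _ldl_symbolic(self.n, self._Ap, self._Ai)
            symbolic = _Symbolic(self.n, Cp.nnz, parent, Lp)
        self.symbolic = symbolic
        self._Lp = symbolic.Lp
        Li, Lx, D, bad = _ldl_numeric(
            self.n, self._Ap, self._Ai, Cp.data.astype(float),
            symbolic.parent, symbolic.Lp
        )
        if bad >= 0:
            raise np.linalg.LinAlgError(
                f"matrix not positive definite at pivot {bad}"
            )
        self._Li, self._Lx, self._D = Li, Lx, D
        self._Zx = None

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self._D)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        one_d = b.ndim == 1
        B = b.reshape(-1, 1) if one_d else b.copy()
        Bp = np.ascontiguousarray(B[self.perm, :])
        _ldl_solve(self.n, self._Lp, self._Li, self._Lx, self._D, Bp)
        out = np.empty_like(Bp)
        out[self.perm, :] = Bp
        return out[:, 0] if one_d else out

    def _ensure_selected_inverse(self):
        if self._Zx is not None:
            return
        n = self.n
        sym = self.symbolic
        if sym.Zp is None:
            # symmetrized filled pattern (both triangles + diagonal), with a
            # mirror map pairing each entry with its transposed position
            Lpat = sp.csc_matrix(
                (np.ones(self._Lp[n]), self._Li, self._Lp), shape=(n, n)
            )
            S = (Lpat + Lpat.T + sp.identity(n, format="csc")).tocsc()
            S.sort_indices()
            S.data = np.arange(S.nnz, dtype=np.float64)
            St = S.T.tocsc()
            St.sort_indices()
            sym.mirror = St.data.astype(np.int64)
            sym.Zp = S.indptr.astype(np.int64)
            sym.Zi = S.indices.astype(np.int64)
        self._Zp, self._Zi = sym.Zp, sym.Zi
        self._Zx = _takahashi_full(
            n, self._Lp, self._Li, self._Lx, self._D,
            self._Zp, self._Zi, sym.mirror,
        )

    def inv_diag(self, idx=None) -> np.ndarray:
        """Diagonal of C^-1 (original ordering)."""
        idx = np.arange(self.n) if idx is None else np.asarray(idx)
        return self.inv_entries(idx, idx)

    def inv_entries(self, rows, cols) -> np.ndarray:
        """Entries of C^-1 at (rows, cols); exact on the filled pattern.

        Requested positions must lie within the sparsity pattern of C
        (which is contained in the filled pattern), as is the case for all
        trace terms in the REML score.
        """
        self._ensure_selected_inverse()
        r = self.iperm[np.asarray(rows, dtype=np.int64)]
        c = self.iperm[np.asarray(cols, dtype=np.int64)]
        return _gather_entries(self._Zp, self._Zi, self._Zx, r, c)
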