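"""Numerator relationship matrix: tabular construction and sparse inverse.

The additive-genetic effects in the mixed model are distributed
N(0, A (x) G) with A the pedigree numerator relationship matrix.  Only
A^-1 enters the mixed-model equations; it is built directly from the
pedigree by Henderson's rules with inbreeding, using the per-animal
Mendelian-sampling variance d_i:

    d_i = 1                                    both parents unknown
    d_i = 1 - 0.25 (1 + F_p)                   one parent p known
    d_i = 1 - 0.25 (1 + F_s) - 0.25 (1 + F_d)  both known

and contributions 1/d_i to (i,i), -0.5/d_i to (i,parent) and 0.25/d_i to
each (parent, parent') pair.  Unknown parents are treated as founders (no
genetic groups).  The dense tabular A serves as a small-scale oracle.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .population import Pedigree, compute_inbreeding

__all__ = ["tabular_A", "a_inverse", "log_det_A"]

_TABULAR_CAP = 2000


def tabular_A(ped: Pedigree, size_cap: int = _TABULAR_CAP) -> np.ndarray:
    """Dense numerator relationship matrix by the recursive tabular method.

    Intended as a test oracle; refuses pedigrees above ``size_cap``.
    """
    n = ped.n
    if n > size_cap:
        raise ValueError(f"tabular_A is an oracle for pedigrees <= {size_cap}")
    A = np.zeros((n + 1, n + 1))  # 1-based with a zero row/col for unknowns
    for i in range(1, n + 1):
        s, d = ped.sire[i - 1], ped.dam[i - 1]
        A[i, i] = 1.0 + 0.5 * A[s, d]
        rows = np.arange(1, i)
        vals = 0.5 * (A[rows, s] + A[rows, d])
        A[rows, i] = vals
        A[i, rows] = vals
    return A[1:, 1:]


def a_inverse(ped: Pedigree) -> sp.csc_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding (see module docs)."""
    if ped.F is None:
        compute_inbreeding(ped)
    n = ped.n
    Fpad = np.concatenate([[0.0], ped.F])
    s, d = ped.sire, ped.dam
    both = (s > 0) & (d > 0)
    one_s = (s > 0) & (d == 0)
    one_d = (s == 0) & (d > 0)
    dvec = np.ones(n)
    dvec[both] = 1.0 - 0.25 * (1 + Fpad[s[both]]) - 0.25 * (1 + Fpad[d[both]])
    dvec[one_s] = 1.0 - 0.25 * (1 + Fpad[s[one_s]])
    dvec[one_d] = 1.0 - 0.25 * (1 + Fpad[d[one_d]])
    if np.any(dvec <= 0):
        raise ValueError("non-positive Mendelian variance; invalid pedigree")
    w = 1.0 / dvec

    rows, cols, vals = [], [], []
    ids0 = np.arange(n)  # zero-based animal indices

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(ids0, ids0, w)
    for parent in (s, d):
        m = parent > 0
        add(ids0[m], parent[m] - 1, -0.5 * w[m])
        add(parent[m] - 1, ids0[m], -0.5 * w[m])
        add(parent[m] - 1, parent[m] - 1, 0.25 * w[m])
    m = both
    add(s[m] - 1, d[m] - 1, 0.25 * w[m])
    add(d[m] - 1, s[m] - 1, 0.25 * w[m])

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def log_det_A(ped: Pedigree) -> float:
    """log|A| = sum_i log d_i from the gene-flow decomposition A = T D T'."""
    from .population import mendelian_variance_coefficients

    return float(np.sum(np.log(mendelian_variance_coefficients(ped))))
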