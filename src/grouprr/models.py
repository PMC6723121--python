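"""Design matrices and mixed-model equations for the two random-regression models.

Individual-record model, for animal i at time t:

    y_it = sum_k phi_tk beta_k + sum_k phi_tk a_ik + sum_k phi_tk pe_ik + e_it

with a ~ N(0, A (x) G), pe ~ N(0, I (x) P), e ~ N(0, I sigma_e2).

Group-record model: the pen's record y*_jt is the sum of its currently
active members' records, so every term is summed over active members: the
additive and permanent-environment covariate rows carry phi(t) in the
coefficient columns of every active member, and the residual variance is
n_jt * sigma_e2 (R = D sigma_e2, D = diag of active group sizes).  The
fixed part is one regression curve per observed group-size class m = n_jt,
which absorbs the group-size main effect (a separate main effect plus
nested intercepts would be confounded).

Henderson's mixed-model equations are

    [ W' R^-1 W + blockdiag(0, A^-1 (x) G^-1, I (x) P^-1) ] s = W' R^-1 y

with W = [X  Z_a  Z_pe]; equations are ordered fixed effects first, then
the 2 additive coefficients of every pedigree animal (coefficients nested
within animal), then the 2 PE coefficients of every animal with at least
one contributing record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .population import Pedigree, TraitParams

__all__ = ["Design", "MMESystem", "aggregate_group_records", "build_design",
           "assemble_mme"]


@dataclass
class Design:
    """Stacked design matrices for either model kind.

    ``r0`` holds the per-row residual weight (1 for individual records,
    n_jt for group records), so R = diag(r0) * sigma_e2.  ``pe_ids`` are
    the animal ids (1-based) with permanent-environment equations, in
    equation order.
    """

    kind: str
    X: sp.csr_matrix
    Za: sp.csr_matrix
    Zp: sp.csr_matrix
    y: np.ndarray
    r0: np.ndarray
    pe_ids: np.ndarray
    n_ped: int
    n_coef: int = 2
    fixed_labels: tuple = ()
    animal_order: np.ndarray | None = None  # preferred elimination order

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def W(self) -> sp.csr_matrix:
        return sp.hstack([self.X, self.Za, self.Zp], format="csr")

    def offsets(self):
        nf = self.n_fixed
        na = self.n_coef * self.n_ped
        return nf, nf + na, nf + na + self.n_coef * len(self.pe_ids)


@dataclass
class MMESystem:
    C: sp.csc_matrix
    rhs: np.ndarray
    design: Design
    params: TraitParams


def aggregate_group_records(phen: pd.DataFrame, pens: pd.DataFrame) -> pd.DataFrame:
    """Sum observed member records per (pen, time).

    Returns a table with columns ``pen``, ``time``, ``y_star``, ``n`` and
    ``members`` (tuple of active member ids).  (pen, time) cells whose
    members have all dropped out are omitted.
    """
    missing = np.setdiff1d(pens["id"].unique(), phen["id"].unique())
    if len(missing):
        raise ValueError(f"pen members without phenotype rows: {missing[:5]}...")
    obs = phen[phen["observed"]]
    merged = obs.merge(pens[["pen", "id"]], on="id", how="inner")
    grouped = merged.groupby(["pen", "time"], sort=True)
    out = grouped.agg(
        y_star=("value", "sum"), n=("id", "size"), members=("id", tuple)
    ).reset_index()
    return out


def _rr_block(row_idx, col_entities, phis, n_entities, n_coef=2):
    """CSR matrix with phi covariates in each entity's coefficient columns."""
    rows = np.repeat(row_idx, n_coef)
    cols = (np.asarray(col_entities)[:, None] * n_coef
            + np.arange(n_coef)[None, :]).ravel()
    vals = np.asarray(phis).ravel()
    n_rows = int(row_idx.max()) + 1 if len(row_idx) else 0
    return sp.coo_matrix(
        (vals, (rows, cols)), shape=(n_rows, n_entities * n_coef)
    ).tocsr()


def build_design(kind: str, data: pd.DataFrame, L: np.ndarray,
                 ped: Pedigree) -> Design:
    """Build X, Z_a, Z_pe, y and the residual weights for one model kind.

    ``data`` is a phenotype table (kind='individual'; unobserved rows are
    skipped) or a group-record table from :func:`aggregate_group_records`
    (kind='group').
    """
    L = np.asarray(L, dtype=float)
    T, k = L.shape
    n_ped = ped.n

    if kind == "individual":
        obs = data[data["observed"]]
        times = obs["time"].to_numpy()
        if times.min() < 1 or times.max() > T:
            raise ValueError("record at a time point outside the basis")
        ids = obs["id"].to_numpy()
        y = obs["value"].to_numpy(dtype=float)
        nrec = len(y)
        phis = L[times - 1]  # nrec x k
        rows = np.arange(nrec)

        X = sp.csr_matrix(phis)
        Za = _rr_block(rows, ids - 1, phis, n_ped, k)
        pe_ids = np.unique(ids)
        slot = {a: s for s, a in enumerate(pe_ids)}
        Zp = _rr_block(rows, np.array([slot[a] for a in ids]), phis,
                       len(pe_ids), k)
        Zp = sp.csr_matrix((Zp.data, Zp.indices, Zp.indptr),
                           shape=(nrec, k * len(pe_ids)))
        return Design(kind, X, Za, Zp, y, np.ones(nrec), pe_ids, n_ped, k,
                      fixed_labels=("overall",))

    if kind != "group":
        raise ValueError(f"unknown model kind {kind!r}")

    rec = data.reset_index(drop=True)
    times = rec["time"].to_numpy()
    if len(rec) == 0:
        raise ValueError("no group records")
    if times.min() < 1 or times.max() > T:
        raise ValueError("record at a time point outside the basis")
    y = rec["y_star"].to_numpy(dtype=float)
    n_jt = rec["n"].to_numpy()
    nrec = len(y)
    phis = L[times - 1]

    # fixed part: one curve per observed size class
    classes = np.unique(n_jt)
    class_of = {c: i for i, c in enumerate(classes)}
    Xrows = np.arange(nrec)
    X = _rr_block(Xrows, np.array([class_of[c] for c in n_jt]), phis,
                  len(classes), k)
    X = sp.csr_matrix((X.data, X.indices, X.indptr),
                      shape=(nrec, k * len(classes)))

    # random parts: summed covariates over active members
    member_rows, member_ids = [], []
    for r, members in enumerate(rec["members"]):
        member_rows.extend([r] * len(members))
        member_ids.extend(members)
    member_rows = np.asarray(member_rows)
    member_ids = np.asarray(member_ids, dtype=np.int64)
    mphis = phis[member_rows]
    Za = _rr_block(member_rows, member_ids - 1, mphis, n_ped, k)
    Za.resize((nrec, k * n_ped))
    pe_ids = np.unique(member_ids)
    slot = {a: s for s, a in enumerate(pe_ids)}
    Zp = _rr_block(member_rows, np.array([slot[a] for a in member_ids]),
                   mphis, len(pe_ids), k)
    Zp.resize((nrec, k * len(pe_ids)))
    # pen-clustered elimination order: pen mates are mutually coupled by the
    # summed records, so eliminating whole pens (youngest pens first) before
    # older animals roughly halves the Cholesky fill
    seen = set()
    animal_order = []
    for _, row in rec.sort_values("pen", ascending=False).iterrows():
        for a in row["members"]:
            if a not in seen:
                seen.add(a)
                animal_order.append(a)
    animal_order.extend(i for i in range(n_ped, 0, -1) if i not in seen)
    return Design(kind, X, Za, Zp, y, n_jt.astype(float), pe_ids, n_ped, k,
                  fixed_labels=tuple(f"size_{c}" for c in classes),
                  animal_order=np.asarray(animal_order, dtype=np.int64))


def mme_elimination_order(design: Design) -> np.ndarray:
    """Fill-reducing elimination order tailored to the MME structure.

    A^-1 factors with zero fill when animals are eliminated youngest
    first (its gene-flow decomposition is triangular in pedigree order),
    so the MME is ordered: per animal, youngest first, the additive
    coefficient pair followed by the animal's PE pair; the (dense) fixed
    equations come last.  This gives far less fill than generic minimum-
    degree orderings on these matrices.
    """
    nf = design.n_fixed
    k = design.n_coef
    n_ped = design.n_ped
    pe_slot = np.full(n_ped + 1, -1, dtype=np.int64)
    pe_slot[design.pe_ids] = np.arange(len(design.pe_ids))
    animals = (design.animal_order if design.animal_order is not None
               else np.arange(n_ped, 0, -1))
    order = []
    off_pe = nf + k * n_ped
    for i in animals:
        base = nf + k * (i - 1)
        order.extend(range(base, base + k))
        s = pe_slot[i]
        if s >= 0:
            order.extend(range(off_pe + k * s, off_pe + k * s + k))
    order.extend(range(nf))
    return np.asarray(order, dtype=np.int64)


def sigma_inv_augmentation(design: Design, a_inv: sp.spmatrix,
                           params: TraitParams) -> sp.csc_matrix:
    """blockdiag(0, A^-1 (x) G^-1, I (x) P^-1) in equation order."""
    Ginv = np.linalg.inv(params.G)
    Pinv = np.linalg.inv(params.P)
    zero = sp.csc_matrix((design.n_fixed, design.n_fixed))
    add = sp.kron(a_inv, Ginv, format="csc")
    pe = sp.kron(sp.identity(len(design.pe_ids), format="csc"), Pinv,
                 format="csc")
    return sp.block_diag([zero, add, pe], format="csc")


def assemble_mme(design: Design, a_inv: sp.spmatrix,
                 params: TraitParams) -> MMESystem:
    """Henderson's mixed-model equations at the given variance components."""
    if np.linalg.det(params.G) <= 0 or np.linalg.det(params.P) <= 0:
        raise ValueError("G and P must be non-singular")
    W = design.W
    rinv = 1.0 / (design.r0 * params.sigma_e2)
    WtRi = W.T.multiply(rinv)  # csc, columns scaled
    C = (WtRi @ W + sigma_inv_augmentation(design, a_inv, params)).tocsc()
    C.sort_indices()
    rhs = np.asarray(WtRi @ design.y).ravel()
    return MMESystem(C=C, rhs=rhs, design=design, params=params)
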