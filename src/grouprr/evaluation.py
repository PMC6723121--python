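"""BLUP solutions, the selection index over the trajectory, and validation.

Breeding values are curves; the per-time-point EBV of animal i is
phi(t)' a_hat_i and the selection index is the weighted sum of the T
per-time-point EBVs (weight 1 each by default), i.e.
(sum_t w_t phi(t))' a_hat_i.  Validation compares estimated with true
indices over the animals that have phenotypic data: accuracy r is the
Pearson correlation, and bias b1 is the slope of regressing the TRUE
index on the ESTIMATED index (1 = unbiased, > 1 = deflated EBVs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._sparseops import SparseLDL
from .models import MMESystem, mme_elimination_order
from .population import AnimalEffects

__all__ = ["EBVTable", "EvalMetrics", "solve_blup", "selection_index",
           "evaluate"]


@dataclass
class EvalMetrics:
    r: float
    b1: float
    n_animals: int


@dataclass
class EBVTable:
    """Estimated additive coefficients and derived EBVs per pedigree animal."""

    a_hat: np.ndarray          # n_ped x 2
    ebv: np.ndarray            # n_ped x T, phi(t)' a_hat
    fixed: np.ndarray          # fixed-effect solutions
    pe_hat: np.ndarray | None = None

    def index(self, L: np.ndarray, weights=None) -> np.ndarray:
        return selection_index(self.a_hat, L, weights)

    def to_frame(self, L: np.ndarray, truth: AnimalEffects | None = None
                 ) -> pd.DataFrame:
        n, T = self.ebv.shape
        df = pd.DataFrame({"id": np.arange(1, n + 1),
                           "a0_hat": self.a_hat[:, 0],
                           "a1_hat": self.a_hat[:, 1]})
        for t in range(T):
            df[f"ebv_t{t + 1}"] = self.ebv[:, t]
        df["index"] = self.index(L)
        if truth is not None:
            df["true_index"] = selection_index(truth.a, L)
        return df


def solve_blup(mme: MMESystem, L: np.ndarray) -> EBVTable:
    """Solve Henderson's equations by sparse LDL' and unpack the solutions."""
    factor = SparseLDL(mme.C, perm=mme_elimination_order(mme.design))
    sol = factor.solve(mme.rhs)
    d = mme.design
    nf, na_end, _ = d.offsets()
    k = d.n_coef
    a_hat = sol[nf:na_end].reshape(d.n_ped, k)
    pe_hat = sol[na_end:].reshape(len(d.pe_ids), k)
    L = np.asarray(L, dtype=float)
    return EBVTable(a_hat=a_hat, ebv=a_hat @ L.T, fixed=sol[:nf],
                    pe_hat=pe_hat)


def selection_index(a_coef: np.ndarray, L: np.ndarray, weights=None
                    ) -> np.ndarray:
    """index_i = sum_t w_t phi(t)' a_i = (L' w)' a_i."""
    L = np.asarray(L, dtype=float)
    T = L.shape[0]
    w = np.ones(T) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != T:
        raise ValueError("weights must have one entry per time point")
    return np.atleast_2d(a_coef) @ (L.T @ w)


def evaluate(index_hat: np.ndarray, index_true: np.ndarray, cohort_idx
             ) -> EvalMetrics:
    """Accuracy and bias of the estimated index over a validation cohort.

    ``cohort_idx`` holds zero-based positions (e.g. ids - 1) of the animals
    with phenotypic data.
    """
    cohort_idx = np.asarray(cohort_idx)
    if len(cohort_idx) == 0:
        raise ValueError("empty validation cohort")
    x = np.asarray(index_hat)[cohort_idx]
    y = np.asarray(index_true)[cohort_idx]
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in an index; metrics undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    b1 = float(np.cov(y, x, ddof=1)[0, 1] / np.var(x, ddof=1))
    return EvalMetrics(r=r, b1=b1, n_animals=len(cohort_idx))
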