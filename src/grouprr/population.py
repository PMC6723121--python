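"""Simulation of a pedigreed pig population with longitudinal phenotypes.

The population has discrete, non-overlapping generations.  Generation 0
consists of unrelated founders; in every later generation a fixed number of
sires is drawn at random from the previous generation's males, each sire is
mated to a fixed number of randomly drawn dams (one parity per dam), and
every mating produces a full-sib litter.  Selection and mating are random,
so there is no genetic trend.

Breeding values are curves: each animal carries a 2-vector of additive
random-regression coefficients (intercept, slope) on the normalized
Legendre basis.  Founder coefficients are drawn from N(0, G); offspring
coefficients are the parent average plus a Mendelian-sampling deviation

    a_i = (a_s + a_d) / 2 + m_i,   m_i ~ N(0, (1/2) (1 - (F_s + F_d)/2) G),

where F_s, F_d are the parents' inbreeding coefficients.  Phenotyped
animals additionally carry permanent-environment coefficients pe ~ N(0, P),
and the phenotype of animal i at time point t is

    y_it = phi_t' a_i + phi_t' pe_i + e_it,   e_it ~ N(0, sigma_e2),

with no interactions and no simulated fixed effects (zero trait mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .basis import TimeGrid, legendre_matrix

__all__ = [
    "TraitParams",
    "Pedigree",
    "AnimalEffects",
    "simulate_pedigree",
    "compute_inbreeding",
    "mendelian_variance_coefficients",
    "simulate_genetic_effects",
    "simulate_pe_and_phenotypes",
]


@dataclass(frozen=True)
class TraitParams:
    """Generating (or estimated) covariance structure of the trait.

    G and P are 2x2 covariance matrices of the intercept and slope
    coefficients for the additive-genetic and permanent-environment curves;
    sigma_e2 is the homogeneous residual variance of a single record.
    """

    G: np.ndarray
    P: np.ndarray
    sigma_e2: float

    def __post_init__(self) -> None:
        G = np.atleast_2d(np.asarray(self.G, dtype=float))
        P = np.atleast_2d(np.asarray(self.P, dtype=float))
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "P", P)
        for name, M in (("G", G), ("P", P)):
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")

    @classmethod
    def default(cls) -> "TraitParams":
        """Covariances of the simulated feed-intake trait (weekly records)."""
        return cls(
            G=np.array([[63.42, -5.42], [-5.42, 6.85]]),
            P=np.array([[30.61, 4.28], [4.28, 29.25]]),
            sigma_e2=53.45,
        )

    def as_theta(self) -> np.ndarray:
        """Pack into the 7-vector (G11, G12, G22, P11, P12, P22, sigma_e2)."""
        return np.array(
            [self.G[0, 0], self.G[0, 1], self.G[1, 1],
             self.P[0, 0], self.P[0, 1], self.P[1, 1], self.sigma_e2]
        )

    @classmethod
    def from_theta(cls, theta) -> "TraitParams":
        t = np.asarray(theta, dtype=float)
        return cls(
            G=np.array([[t[0], t[1]], [t[1], t[2]]]),
            P=np.array([[t[3], t[4]], [t[4], t[5]]]),
            sigma_e2=float(t[6]),
        )


@dataclass
class Pedigree:
    """Animal / sire / dam records, parents-before-offspring.

    Ids are 1..n; 0 denotes an unknown parent.  ``sex`` is 1 for males and
    2 for females; ``litter`` is 0 for founders.  ``F`` (inbreeding) is
    filled in by :func:`compute_inbreeding`.
    """

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    litter: np.ndarray
    F: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.sire)
        ids = np.arange(1, n + 1)
        if np.any(self.sire >= ids) or np.any(self.dam >= ids):
            raise ValueError("parents must precede offspring (sire, dam < id)")

    @property
    def n(self) -> int:
        return len(self.sire)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    def generation_ids(self, g: int) -> np.ndarray:
        return self.ids[self.generation == g]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": self.sire,
                "dam": self.dam,
                "sex": self.sex,
                "generation": self.generation,
                "litter": self.litter,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class AnimalEffects:
    """True simulated regression coefficients.

    ``a`` is n x 2 over the whole pedigree; ``pe`` is n x 2 with rows only
    filled for phenotyped animals (zero elsewhere), ``phenotyped`` marks
    which rows are meaningful.
    """

    a: np.ndarray
    pe: np.ndarray | None = None
    phenotyped: np.ndarray | None = None


def simulate_pedigree(
    n_generations: int,
    n_sires: int,
    n_dams_per_sire: int,
    litter_size: int,
    seed,
) -> Pedigree:
    """Simulate the discrete-generation pedigree.

    Generation 0 holds ``n_sires`` unrelated founder males and
    ``n_sires * n_dams_per_sire`` founder females.  Each of generations
    1..n_generations-1 is produced by randomly selecting sires and dams
    from the immediately preceding generation (random mating, one parity).
    """
    if min(n_generations, n_sires, n_dams_per_sire, litter_size) < 1:
        raise ValueError("all design counts must be >= 1")
    rng = np.random.default_rng(seed)
    n_dams = n_sires * n_dams_per_sire

    sire = [np.zeros(n_sires + n_dams, dtype=np.int64)]
    dam = [np.zeros(n_sires + n_dams, dtype=np.int64)]
    sex = [np.concatenate([np.ones(n_sires, dtype=np.int64),
                           np.full(n_dams, 2, dtype=np.int64)])]
    gen = [np.zeros(n_sires + n_dams, dtype=np.int64)]
    litter = [np.zeros(n_sires + n_dams, dtype=np.int64)]

    prev_ids = np.arange(1, n_sires + n_dams + 1)
    prev_sex = sex[0]
    next_id = n_sires + n_dams + 1
    litter_counter = 0
    for g in range(1, n_generations):
        males = prev_ids[prev_sex == 1]
        females = prev_ids[prev_sex == 2]
        if len(males) < n_sires or len(females) < n_dams:
            raise ValueError(
                f"generation {g - 1} has too few males ({len(males)}) or "
                f"females ({len(females)}) to produce generation {g}"
            )
        sel_sires = rng.choice(males, size=n_sires, replace=False)
        sel_dams = rng.permutation(rng.choice(females, size=n_dams, replace=False))

        n_off = n_dams * litter_size
        g_sire = np.repeat(np.repeat(sel_sires, n_dams_per_sire), litter_size)
        g_dam = np.repeat(sel_dams, litter_size)
        g_litter = np.repeat(
            np.arange(litter_counter + 1, litter_counter + n_dams + 1), litter_size
        )
        litter_counter += n_dams
        g_sex = rng.integers(1, 3, size=n_off)

        sire.append(g_sire)
        dam.append(g_dam)
        sex.append(g_sex.astype(np.int64))
        gen.append(np.full(n_off, g, dtype=np.int64))
        litter.append(g_litter)

        prev_ids = np.arange(next_id, next_id + n_off)
        prev_sex = g_sex
        next_id += n_off

    return Pedigree(
        sire=np.concatenate(sire),
        dam=np.concatenate(dam),
        sex=np.concatenate(sex),
        generation=np.concatenate(gen),
        litter=np.concatenate(litter),
    )


@njit(cache=False)
def _inbreeding_ml(sire, dam):  # pragma: no cover - numba kernel
    """Meuwissen-Luo style inbreeding: F_i = A_ii - 1 from A = T D T'."""
    n = sire.shape[0]
    F = np.zeros(n + 1)
    d = np.zeros(n + 1)  # Mendelian variance coefficients, 1-based
    coeff = np.zeros(n + 1)
    for i in range(1, n + 1):
        s, dd = sire[i - 1], dam[i - 1]
        if s == 0 and dd == 0:
            d[i] = 1.0
        elif s == 0:
            d[i] = 0.75 - 0.25 * F[dd]
        elif dd == 0:
            d[i] = 0.75 - 0.25 * F[s]
        else:
            d[i] = 0.5 - 0.25 * (F[s] + F[dd])
        if s == 0 or dd == 0:
            F[i] = 0.0
            continue
        # row i of the gene-flow matrix T, traversed top-down from i
        coeff[: i + 1] = 0.0
        coeff[i] = 1.0
        aii = 0.0
        for j in range(i, 0, -1):
            c = coeff[j]
            if c == 0.0:
                continue
            js, jd = sire[j - 1], dam[j - 1]
            if js > 0:
                coeff[js] += 0.5 * c
            if jd > 0:
                coeff[jd] += 0.5 * c
            aii += c * c * d[j]
        F[i] = aii - 1.0
    return F[1:], d[1:]


def mendelian_variance_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-animal Mendelian-sampling variance ratio d_i (diag of D in A=TDT')."""
    if ped.F is None:
        compute_inbreeding(ped)
    Fpad = np.concatenate([[0.0], ped.F])
    s, d = ped.sire, ped.dam
    out = np.where(
        (s == 0) & (d == 0),
        1.0,
        np.where(
            s == 0,
            0.75 - 0.25 * Fpad[d],
            np.where(d == 0, 0.75 - 0.25 * Fpad[s],
                     0.5 - 0.25 * (Fpad[s] + Fpad[d])),
        ),
    )
    return out


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Compute inbreeding coefficients F for every animal (stored on ``ped``).

    Uses the gene-flow decomposition A = T D T' so F_i = A_ii - 1, which is
    exact and O(n * ancestors).
    """
    F, _ = _inbreeding_ml(ped.sire, ped.dam)
    ped.F = F
    return F


def simulate_genetic_effects(ped: Pedigree, G: np.ndarray, seed) -> np.ndarray:
    """Sample additive regression coefficients for every animal in the pedigree.

    Founders ~ N(0, G); offspring = parent average + Mendelian deviation
    with covariance (1/2)(1 - (F_s + F_d)/2) G.  Returns an n x 2 array.
    """
    G = np.asarray(G, dtype=float)
    if np.any(np.linalg.eigvalsh(G) < 0):
        raise ValueError("G must be positive semi-definite")
    if ped.F is None:
        compute_inbreeding(ped)
    rng = np.random.default_rng(seed)
    k = G.shape[0]
    # allow a zero matrix in degenerate tests
    w, V = np.linalg.eigh(G)
    cholG = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    n = ped.n
    a = np.zeros((n, k))
    Fpad = np.concatenate([[0.0], ped.F])
    apad = np.zeros((n + 1, k))
    for g in np.unique(ped.generation):
        mask = ped.generation == g
        idx = np.nonzero(mask)[0]
        z = rng.standard_normal((len(idx), k))
        s, d = ped.sire[idx], ped.dam[idx]
        founder = (s == 0) & (d == 0)
        if np.any(founder):
            a[idx[founder]] = z[founder] @ cholG.T
        off = ~founder
        if np.any(off):
            io = idx[off]
            so, do = s[off], d[off]
            pa = 0.5 * (apad[so] + apad[do])
            fbar = 0.5 * (Fpad[so] + Fpad[do])
            scale = np.sqrt(0.5 * (1.0 - fbar))[:, None]
            a[io] = pa + scale * (z[off] @ cholG.T)
        apad[idx + 1] = a[idx]
    return a


def simulate_pe_and_phenotypes(
    ped: Pedigree,
    effects: AnimalEffects,
    params: TraitParams,
    L: np.ndarray,
    phenotyped_generations,
    seed,
) -> pd.DataFrame:
    """Simulate PE coefficients and longitudinal records for selected generations.

    Returns a long-format table with columns ``id``, ``time`` (1..T),
    ``value`` and ``observed`` (all True here; drop-out masks later), and
    fills ``effects.pe`` / ``effects.phenotyped``.
    """
    rng = np.random.default_rng(seed)
    L = np.asarray(L, dtype=float)
    T, k = L.shape
    gens = np.asarray(phenotyped_generations)
    if not np.isin(gens, np.unique(ped.generation)).all():
        raise ValueError("phenotyped generation absent from pedigree")
    mask = np.isin(ped.generation, gens)
    idx = np.nonzero(mask)[0]
    n_ph = len(idx)

    w, V = np.linalg.eigh(params.P)
    cholP = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    pe = rng.standard_normal((n_ph, k)) @ cholP.T
    e = rng.standard_normal((n_ph, T)) * np.sqrt(params.sigma_e2)

    y = (effects.a[idx] + pe) @ L.T + e  # n_ph x T

    effects.pe = np.zeros_like(effects.a)
    effects.pe[idx] = pe
    effects.phenotyped = mask.copy()

    ids = np.repeat(idx + 1, T)
    times = np.tile(np.arange(1, T + 1), n_ph)
    return pd.DataFrame(
        {
            "id": ids,
            "time": times,
            "value": y.ravel(),
            "observed": np.ones(n_ph * T, dtype=bool),
        }
    )


def default_time_grid(T: int = 6) -> TimeGrid:
    """Weekly test time points 1..T (T=6 in the study design)."""
    return TimeGrid(np.arange(1, T + 1))


def default_basis(T: int = 6, order: int = 1) -> np.ndarray:
    return legendre_matrix(default_time_grid(T), order)
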