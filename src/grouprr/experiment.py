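"""Scenario orchestration: simulate -> group -> drop -> REML -> BLUP -> validate.

A :class:`ScenarioConfig` fully determines one cell of the study design
(grouping scenario x drop-out strategy) at a given population scale;
:func:`run_scenario` executes the replicates and summarizes each estimated
variance component and the evaluation metrics as mean and SD over
replicates.

Seeding: replicate k of a scenario draws its stage streams (pedigree,
breeding values, phenotypes, grouping, drop-out) from
``SeedSequence([master_seed, k])``, so any single replicate is
reproducible in isolation and the full grid is deterministic given the
master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import heritability_trajectory, legendre_matrix
from .population import (TraitParams, compute_inbreeding, simulate_pedigree,
                         simulate_genetic_effects, simulate_pe_and_phenotypes,
                         AnimalEffects, default_time_grid)
from .grouping import (assign_pens, plan_dropout_random,
                       plan_dropout_phenotypic, apply_dropout)
from .relationship import a_inverse, log_det_A
from .models import aggregate_group_records, build_design, assemble_mme
from .reml import estimate_vc, REMLOptions, REMLResult
from .evaluation import solve_blup, selection_index, evaluate

__all__ = ["ScenarioConfig", "ReplicateResult", "run_replicate",
           "run_scenario", "summarize_replicates", "REDUCED_SCALE",
           "PAPER_SCALE"]

THETA_NAMES = ("G11", "G12", "G22", "P11", "P12", "P22", "sigma_e2")

# population-scale profiles: (generations, sires, dams/sire, litter,
# phenotyped generations)
REDUCED_SCALE = dict(n_generations=6, n_sires=10, n_dams_per_sire=10,
                     litter_size=6, n_pheno_generations=3)
PAPER_SCALE = dict(n_generations=11, n_sires=30, n_dams_per_sire=20,
                   litter_size=6, n_pheno_generations=5)


@dataclass
class ScenarioConfig:
    n_generations: int = 6
    n_sires: int = 10
    n_dams_per_sire: int = 10
    litter_size: int = 6
    n_pheno_generations: int = 3
    grouping: str = "individual"   # individual | group3x4 | group6x2 | group1x12
    dropout: str = "none"          # none | random | phenotypic
    dropout_proportion: float = 0.15
    T: int = 6
    order: int = 1
    replicates: int = 5
    master_seed: int = 1
    params: TraitParams = field(default_factory=TraitParams.default)
    blup_at_true_vc: bool = False
    reml_options: REMLOptions = field(default_factory=REMLOptions)

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)

    @property
    def pheno_generations(self) -> np.ndarray:
        return np.arange(self.n_generations - self.n_pheno_generations,
                         self.n_generations)


@dataclass
class ReplicateResult:
    replicate: int
    theta_hat: np.ndarray
    reml: REMLResult
    metrics: "EvalMetrics"
    h2_hat: np.ndarray

    def row(self) -> dict:
        d = {"replicate": self.replicate}
        d.update(dict(zip(THETA_NAMES, self.theta_hat)))
        d.update({"r": self.metrics.r, "b1": self.metrics.b1,
                  "converged": self.reml.converged,
                  "n_iter": self.reml.n_iter})
        return d


def simulate_replicate(cfg: ScenarioConfig, replicate: int):
    """Stages 1-3: pedigree, effects, phenotypes, grouping and drop-out.

    Returns (ped, effects, phen, pens) with drop-out already applied;
    ``pens`` is None for the individual-record model.
    """
    streams = np.random.SeedSequence([cfg.master_seed, replicate]).spawn(5)
    ped = simulate_pedigree(cfg.n_generations, cfg.n_sires,
                            cfg.n_dams_per_sire, cfg.litter_size, streams[0])
    compute_inbreeding(ped)
    L = legendre_matrix(default_time_grid(cfg.T), cfg.order)
    a = simulate_genetic_effects(ped, cfg.params.G, streams[1])
    effects = AnimalEffects(a=a)
    phen = simulate_pe_and_phenotypes(ped, effects, cfg.params, L,
                                      cfg.pheno_generations, streams[2])

    pens = None
    if cfg.grouping != "individual":
        parts = []
        offset = 0
        pen_seeds = streams[3].spawn(len(cfg.pheno_generations))
        for s, g in zip(pen_seeds, cfg.pheno_generations):
            p = assign_pens(ped, int(g), cfg.grouping, s)
            p["pen"] += offset
            offset = p["pen"].max() + 1
            parts.append(p)
        pens = pd.concat(parts, ignore_index=True)

    cohort = phen["id"].unique()
    if cfg.dropout == "random":
        plan = plan_dropout_random(cohort, cfg.dropout_proportion, cfg.T,
                                   streams[4])
        phen = apply_dropout(phen, plan)
    elif cfg.dropout == "phenotypic":
        plan = plan_dropout_phenotypic(phen, cohort, cfg.dropout_proportion,
                                       cfg.T, streams[4])
        phen = apply_dropout(phen, plan)
    elif cfg.dropout != "none":
        raise ValueError(f"unknown dropout strategy {cfg.dropout!r}")
    return ped, effects, phen, pens


def run_replicate(cfg: ScenarioConfig, replicate: int) -> ReplicateResult:
    ped, effects, phen, pens = simulate_replicate(cfg, replicate)
    L = legendre_matrix(default_time_grid(cfg.T), cfg.order)

    if cfg.grouping == "individual":
        design = build_design("individual", phen, L, ped)
    else:
        groups = aggregate_group_records(phen, pens)
        design = build_design("group", groups, L, ped)

    ainv = a_inverse(ped)
    ldA = log_det_A(ped)
    reml = estimate_vc(design, ainv, ldA, options=cfg.reml_options)

    fit_params = cfg.params if cfg.blup_at_true_vc else reml.params
    mme = assemble_mme(design, ainv, fit_params)
    ebv = solve_blup(mme, L)

    idx_hat = ebv.index(L)
    idx_true = selection_index(effects.a, L)
    # animals having phenotypic data: >= 1 record entering the analysis
    observed_ids = (phen.loc[phen["observed"], "id"].unique()
                    if cfg.grouping == "individual" else design.pe_ids)
    metrics = evaluate(idx_hat, idx_true, np.asarray(observed_ids) - 1)

    h2_hat = heritability_trajectory(reml.params.G, reml.params.P,
                                     reml.params.sigma_e2, L)
    return ReplicateResult(replicate=replicate, theta_hat=reml.theta,
                           reml=reml, metrics=metrics, h2_hat=h2_hat)


def run_scenario(cfg: ScenarioConfig, on_error: str = "warn"
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all replicates of one scenario.

    Returns (per_replicate, summary).  A failing replicate is recorded and
    skipped (``on_error='warn'``) or re-raised (``on_error='raise'``).
    """
    rows = []
    for k in range(cfg.replicates):
        try:
            rows.append(run_replicate(cfg, k).row())
        except Exception:
            if on_error == "raise":
                raise
            import warnings

            warnings.warn(f"replicate {k} failed; summary excludes it")
    per_rep = pd.DataFrame(rows)
    return per_rep, summarize_replicates(per_rep)


def summarize_replicates(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (n-1) of every numeric column over replicates."""
    if len(per_rep) == 0:
        raise ValueError("no successful replicates to summarize")
    cols = [c for c in per_rep.columns
            if c not in ("replicate", "converged", "n_iter")]
    mean = per_rep[cols].mean()
    sd = (per_rep[cols].std(ddof=1) if len(per_rep) > 1
          else pd.Series(0.0, index=cols))
    out = pd.DataFrame({"mean": mean, "sd": sd})
    out["n_replicates"] = len(per_rep)
    out["single_replicate_sd_flag"] = len(per_rep) == 1
    return out
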