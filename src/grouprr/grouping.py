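"""Pen allocation and drop-out mechanisms for group-recorded phenotypes.

Twelve phenotyped animals of the same generation form a pen.  Three
allocation scenarios vary the genetic relatedness of pen mates:

* ``group3x4`` — every litter of 6 is split at random into two sub-litters
  of 3; a pen is 4 sub-litters from 4 different litters (medium within- and
  across-pen relationship).
* ``group6x2`` — a pen is the 6 + 6 animals of two whole litters (high
  within-pen relationship).
* ``group1x12`` — a pen is 12 animals from 12 different litters (low
  within-pen relationship).

Drop-out removes 15% of the phenotyped cohort part-way through the test;
records from the drop-out time point onward are missing, and the animal no
longer contributes to its pen's summed record.  ``random`` drop-out picks
animals and times uniformly; ``phenotypic`` drop-out removes, at each time
point, a Poisson-distributed number of the currently lowest-phenotype
animals (emulating culling of poor performers).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .population import Pedigree

__all__ = [
    "assign_pens",
    "plan_dropout_random",
    "plan_dropout_phenotypic",
    "apply_dropout",
    "PEN_SIZE",
    "GROUPING_SCENARIOS",
]

PEN_SIZE = 12
GROUPING_SCENARIOS = ("group3x4", "group6x2", "group1x12")


def _partition_distinct_labels(item_ids, labels, items_per_pen, rng, max_tries=20000):
    """Partition items into pens of ``items_per_pen`` with all labels distinct
    within a pen.  Shuffle first, then repair collisions by pairwise swaps."""
    n = len(item_ids)
    if n % items_per_pen:
        raise ValueError("item count not divisible by pen size")
    order = rng.permutation(n)
    pens = order.reshape(-1, items_per_pen)
    n_pens = pens.shape[0]
    labels = np.asarray(labels)
    if n_pens > 1 and len(np.unique(labels)) < items_per_pen:
        raise ValueError("fewer distinct litters than required per pen")

    def dup_position(p):
        lab = labels[pens[p]]
        _, first = np.unique(lab, return_index=True)
        dup = np.setdiff1d(np.arange(items_per_pen), first, assume_unique=False)
        return dup[0] if len(dup) else -1

    bad = [p for p in range(n_pens) if dup_position(p) >= 0]
    tries = 0
    while bad:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not build litter-distinct pens (infeasible design?)")
        p = bad[-1]
        i = dup_position(p)
        if i < 0:
            bad.pop()
            continue
        q = int(rng.integers(n_pens))
        if q == p:
            continue
        j = int(rng.integers(items_per_pen))
        li, lj = labels[pens[p, i]], labels[pens[q, j]]
        lab_p = labels[pens[p]]
        lab_q = labels[pens[q]]
        # swap only if it removes the duplicate in p without creating one in q
        if lj not in np.delete(lab_p, i) and li not in np.delete(lab_q, j):
            pens[p, i], pens[q, j] = pens[q, j], pens[p, i]
            if dup_position(q) >= 0 and q not in bad:
                bad.append(q)
    return pens


def assign_pens(ped: Pedigree, generation: int, scenario: str, seed) -> pd.DataFrame:
    """Allocate one generation's animals to pens of 12 under a scenario.

    Returns a long table with columns ``pen``, ``generation``, ``id``,
    ``litter``.  Pen ids are unique within the call (generation-local).
    """
    if scenario not in GROUPING_SCENARIOS:
        raise ValueError(f"unknown grouping scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    ids = ped.generation_ids(generation)
    if len(ids) == 0 or len(ids) % PEN_SIZE:
        raise ValueError("generation size must be a positive multiple of 12")
    litters = ped.litter[ids - 1]

    if scenario == "group6x2":
        litter_ids = np.unique(litters)
        for lid in litter_ids:
            if np.sum(litters == lid) != 6:
                raise ValueError("group6x2 requires whole litters of size 6")
        if len(litter_ids) % 2:
            raise ValueError("group6x2 requires an even number of litters")
        order = rng.permutation(litter_ids)
        pen_of_litter = {lid: p for p, pair in enumerate(order.reshape(-1, 2))
                         for lid in pair}
        pen = np.array([pen_of_litter[l] for l in litters])
        out_ids = ids
    elif scenario == "group1x12":
        # pens hold positional indices into ids
        pens = _partition_distinct_labels(ids, litters, PEN_SIZE, rng)
        pen = np.repeat(np.arange(pens.shape[0]), PEN_SIZE)
        out_ids = ids[pens.ravel()]
    else:  # group3x4: random 3+3 split of each litter, 4 sub-litters per pen
        sub_items = []   # list of member-id triples
        sub_labels = []
        for lid in np.unique(litters):
            members = ids[litters == lid]
            if len(members) != 6:
                raise ValueError("group3x4 requires whole litters of size 6")
            perm = rng.permutation(members)
            sub_items.extend([perm[:3], perm[3:]])
            sub_labels.extend([lid, lid])
        pens = _partition_distinct_labels(
            np.arange(len(sub_items)), sub_labels, 4, rng
        )
        pen = np.repeat(np.arange(pens.shape[0]), PEN_SIZE)
        out_ids = np.concatenate(
            [np.concatenate([sub_items[i] for i in row]) for row in pens]
        )

    df = pd.DataFrame(
        {
            "pen": pen,
            "generation": generation,
            "id": out_ids,
            "litter": ped.litter[out_ids - 1],
        }
    )
    # sanity: exact partition
    assert sorted(df["id"]) == sorted(ids)
    return df


def plan_dropout_random(cohort_ids, proportion: float, T: int, seed) -> pd.DataFrame:
    """Uniformly random drop-out: round(proportion * N) animals, each with a
    drop-out time sampled uniformly from {1..T}."""
    if not 0 <= proportion < 1:
        raise ValueError("proportion must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cohort_ids = np.asarray(cohort_ids)
    n_drop = int(round(proportion * len(cohort_ids)))
    chosen = rng.choice(cohort_ids, size=n_drop, replace=False)
    times = rng.integers(1, T + 1, size=n_drop)
    return pd.DataFrame(
        {"id": chosen, "drop_time": times, "strategy": "random"}
    ).sort_values("id", ignore_index=True)


def plan_dropout_phenotypic(
    phen: pd.DataFrame, cohort_ids, proportion: float, T: int, seed
) -> pd.DataFrame:
    """Phenotype-ranked drop-out.

    At each time point t the number of drop-outs is Poisson with mean
    proportion * N / T; the not-yet-dropped animals with the lowest
    phenotype at t are removed with drop-out time t (ties broken by id).
    """
    if not 0 <= proportion < 1:
        raise ValueError("proportion must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cohort_ids = np.asarray(cohort_ids)
    wide = (
        phen[phen["id"].isin(cohort_ids)]
        .pivot(index="id", columns="time", values="value")
    )
    if wide.isna().any().any() or len(wide) != len(cohort_ids):
        raise ValueError("phenotypes must be complete for the cohort")
    mean_per_t = proportion * len(cohort_ids) / T

    remaining = wide.sort_index()
    dropped_ids, dropped_times = [], []
    for t in range(1, T + 1):
        c = int(rng.poisson(mean_per_t))
        if c == 0:
            continue
        if c > len(remaining):
            warnings.warn(
                f"drop-out count {c} at time {t} exceeds remaining "
                f"{len(remaining)} animals; truncating"
            )
            c = len(remaining)
        order = remaining[t].reset_index().sort_values(
            [t, "id"], kind="mergesort"
        )
        drop = order["id"].to_numpy()[:c]
        dropped_ids.extend(drop.tolist())
        dropped_times.extend([t] * c)
        remaining = remaining.drop(index=drop)
    return pd.DataFrame(
        {"id": dropped_ids, "drop_time": dropped_times, "strategy": "phenotypic"}
    ).astype({"id": np.int64, "drop_time": np.int64}, errors="ignore")


def apply_dropout(phen: pd.DataFrame, plan: pd.DataFrame) -> pd.DataFrame:
    """Mask records at t >= drop_time for every planned drop-out animal."""
    out = phen.copy()
    if len(plan) == 0:
        return out
    if not np.isin(plan["id"], phen["id"].unique()).all():
        raise ValueError("drop-out plan contains animals without phenotypes")
    dt = out["id"].map(plan.set_index("id")["drop_time"])
    out["observed"] = out["observed"] & ~(out["time"] >= dt).fillna(False)
    return out
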