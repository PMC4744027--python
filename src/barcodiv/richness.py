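"""Incidence-based species richness and elevational turnover.

The estimators follow the classic incidence (sample-based) conventions, as
popularised by the ``specpool`` function of the vegan R package: with
``S_obs`` observed species over ``m`` sampling units, ``q1`` species found
in exactly one unit (uniques) and ``q2`` in exactly two (duplicates),

* Chao2 (small-sample corrected):  S_obs + ((m-1)/m) * q1^2 / (2 q2),
  falling back to S_obs + ((m-1)/m) * q1 (q1 - 1) / 2 when q2 = 0;
* first-order jackknife:           S_obs + q1 (m-1)/m;
* second-order jackknife:          S_obs + q1 (2m-3)/m - q2 (m-2)^2 / (m (m-1)).

Standard errors use the matching specpool variance expressions (none is
defined for the second-order jackknife). Accumulation curves are
sample-based with the x-axis expressed in cumulative analysed individuals;
richness standardization draws individuals without replacement from one
elevation's specimen pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .partition import Partition

logger = logging.getLogger(__name__)

STANDARD_METHODS = ("sweep", "beating", "hand")


@dataclass(frozen=True)
class IncidenceMatrix:
    """Species x sampling-unit presence/absence."""

    species_ids: Tuple[str, ...]
    unit_ids: Tuple[str, ...]
    presence: np.ndarray  # bool, shape (S, m)

    def __post_init__(self):
        if self.presence.shape != (len(self.species_ids), len(self.unit_ids)):
            raise ValueError("presence matrix shape mismatch")
        if len(self.unit_ids) < 1:
            raise ValueError("incidence matrix needs at least one unit")
        if self.presence.ndim != 2 or (~self.presence.any(axis=1)).any():
            raise ValueError("incidence matrix contains an all-zero species row")

    @property
    def m(self) -> int:
        return len(self.unit_ids)

    @property
    def s_obs(self) -> int:
        return len(self.species_ids)

    @property
    def unit_frequencies(self) -> np.ndarray:
        """Number of units each species occupies."""
        return self.presence.sum(axis=1)

    def q(self, k: int) -> int:
        """Number of species occurring in exactly ``k`` units."""
        return int((self.unit_frequencies == k).sum())


def build_incidence(
    p: Partition,
    meta: pd.DataFrame,
    methods: Optional[Sequence[str]] = STANDARD_METHODS,
    levels: Optional[Sequence[int]] = None,
) -> IncidenceMatrix:
    """Species x unit incidence from a partition plus specimen metadata.

    ``meta`` needs columns ``specimen_id``, ``sampling_unit``, ``method``,
    ``level``. Units are restricted to the given collection methods (pass
    ``None`` to keep all) and, optionally, elevation levels; species absent
    from every retained unit are dropped with a logged count.
    """
    required = {"specimen_id", "sampling_unit", "method", "level"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks columns: {sorted(missing)}")
    sub = meta[meta["specimen_id"].isin(p.specimens)].copy()
    if methods is not None:
        sub = sub[sub["method"].isin(methods)]
    if levels is not None:
        sub = sub[sub["level"].isin(levels)]
    if sub.empty:
        raise ValueError("no sampling units remain after filtering")
    sub["group"] = [p.label_of(s) for s in sub["specimen_id"]]
    units = tuple(sorted(sub["sampling_unit"].unique()))
    unit_idx = {u: k for k, u in enumerate(units)}
    groups = tuple(sorted(sub["group"].unique()))
    group_idx = {g: k for k, g in enumerate(groups)}
    mat = np.zeros((len(groups), len(units)), dtype=bool)
    for g, u in zip(sub["group"], sub["sampling_unit"]):
        mat[group_idx[g], unit_idx[u]] = True
    dropped = p.n_groups - len(groups)
    if dropped:
        logger.info("dropped %d groups absent from retained units", dropped)
    return IncidenceMatrix(groups, units, mat)


@dataclass(frozen=True)
class RichnessEstimate:
    estimator: str
    s_obs: int
    estimate: float
    se: Optional[float]


def chao2(inc: IncidenceMatrix) -> RichnessEstimate:
    """Small-sample-corrected Chao2 with the specpool-convention SE."""
    m = inc.m
    if m < 2:
        raise ValueError("chao2 needs at least two sampling units")
    s, q1, q2 = inc.s_obs, inc.q(1), inc.q(2)
    ssc = (m - 1) / m
    if q2 > 0:
        est = s + ssc * q1 * q1 / (2 * q2)
        g = q1 / q2
        var = q1 * ssc * (0.5 + ssc * (1 + g / 4) * g) * g
    else:
        est = s + ssc * q1 * (q1 - 1) / 2
        var = ssc * (
            ssc * (q1 * (2 * q1 - 1) ** 2 / 4 - q1**4 / (4 * est)) + q1 * (q1 - 1) / 2
        )
    return RichnessEstimate("chao2", s, est, math.sqrt(max(var, 0.0)))


def jackknife(inc: IncidenceMatrix, order: int = 1) -> RichnessEstimate:
    """First- or second-order incidence jackknife (specpool convention;
    no SE is defined for order 2)."""
    m = inc.m
    if order not in (1, 2):
        raise ValueError("jackknife order must be 1 or 2")
    if m < order + 1:
        raise ValueError(f"jackknife order {order} needs at least {order + 1} units")
    s, q1, q2 = inc.s_obs, inc.q(1), inc.q(2)
    if order == 1:
        est = s + q1 * (m - 1) / m
        uniques = inc.presence[inc.unit_frequencies == 1]
        per_unit = uniques.sum(axis=0)  # uniques contributed by each unit
        var = (float((per_unit.astype(float) ** 2).sum()) - q1 / m) * (m - 1) / m
        return RichnessEstimate("jack1", s, est, math.sqrt(max(var, 0.0)))
    est = s + q1 * (2 * m - 3) / m - q2 * (m - 2) ** 2 / (m * (m - 1))
    return RichnessEstimate("jack2", s, est, None)


# --------------------------------------------------------------------------- #
# accumulation & standardization
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class AccumulationCurve:
    """Sample-based accumulation expressed against analysed individuals."""

    method: str
    individuals: np.ndarray  # cumulative individuals at each step
    mean_species: np.ndarray
    lo: np.ndarray  # 2.5 percentile ("collector": equal to the mean)
    hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individuals": self.individuals,
                "mean_species": self.mean_species,
                "lo95": self.lo,
                "hi95": self.hi,
            }
        )


def accumulation_curve(
    inc: IncidenceMatrix,
    specimens_per_unit: Dict[str, int],
    method: str = "random",
    n_perm: int = 1000,
    seed: int | None = None,
) -> AccumulationCurve:
    """Accumulate sampling units and track distinct species.

    ``random`` adds units in ``n_perm`` random orders and reports the mean
    and 2.5/97.5 percentiles per step; ``collector`` adds units in the order
    they appear in the matrix.
    """
    if method not in ("random", "collector"):
        raise ValueError(f"unknown accumulation method {method!r}")
    counts = np.array([specimens_per_unit[u] for u in inc.unit_ids], dtype=float)
    pres = inc.presence
    m = inc.m
    if method == "collector":
        order = np.arange(m)
        seen = np.cumsum(pres[:, order], axis=1) > 0
        species = seen.sum(axis=0).astype(float)
        individuals = np.cumsum(counts[order])
        return AccumulationCurve("collector", individuals, species, species, species)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 for method 'random'")
    rng = np.random.default_rng(seed)
    all_species = np.empty((n_perm, m))
    all_inds = np.empty((n_perm, m))
    for r in range(n_perm):
        order = rng.permutation(m)
        seen = np.cumsum(pres[:, order], axis=1) > 0
        all_species[r] = seen.sum(axis=0)
        all_inds[r] = np.cumsum(counts[order])
    return AccumulationCurve(
        "random",
        all_inds.mean(axis=0),
        all_species.mean(axis=0),
        np.percentile(all_species, 2.5, axis=0),
        np.percentile(all_species, 97.5, axis=0),
    )


def expected_accumulation(inc: IncidenceMatrix, k: int) -> float:
    """Closed-form sample-based rarefaction: E[species after k of m units]."""
    m = inc.m
    freq = inc.unit_frequencies
    total = math.comb(m, k)
    exp = 0.0
    for f in freq:
        exp += 1.0 - math.comb(m - int(f), k) / total if m - f >= k else 1.0
    return exp


@dataclass(frozen=True)
class StandardizedRichness:
    n_draw: int
    reps: int
    mean: float
    lo: float
    hi: float


def standardized_richness(
    p: Partition,
    meta: pd.DataFrame,
    level: int,
    n_draw: int,
    reps: int = 10000,
    seed: int | None = None,
) -> StandardizedRichness:
    """Mean distinct groups among ``n_draw`` individuals drawn without
    replacement from one elevation level's specimen pool (percentile CI)."""
    pool = meta[meta["level"] == level]["specimen_id"].tolist()
    pool = [s for s in pool if s in p.specimens]
    if n_draw > len(pool):
        raise ValueError(
            f"n_draw {n_draw} exceeds pool of {len(pool)} specimens at level {level}"
        )
    codes = np.array(
        pd.factorize(np.array([p.label_of(s) for s in pool]))[0]
    )
    rng = np.random.default_rng(seed)
    richness = np.empty(reps, dtype=int)
    n = len(pool)
    for r in range(reps):
        draw = rng.choice(n, size=n_draw, replace=False)
        richness[r] = len(np.unique(codes[draw]))
    return StandardizedRichness(
        n_draw,
        reps,
        float(richness.mean()),
        float(np.percentile(richness, 2.5)),
        float(np.percentile(richness, 97.5)),
    )


def expected_standardized_richness(
    p: Partition, meta: pd.DataFrame, level: int, n_draw: int
) -> float:
    """Exact expectation sum_s [1 - C(N - a_s, n) / C(N, n)] over groups."""
    pool = [s for s in meta[meta["level"] == level]["specimen_id"] if s in p.specimens]
    n_total = len(pool)
    sizes = pd.Series([p.label_of(s) for s in pool]).value_counts()
    denom = math.comb(n_total, n_draw)
    return float(
        sum(1.0 - math.comb(n_total - a, n_draw) / denom if n_total - a >= n_draw
            else 1.0
            for a in sizes)
    )


# --------------------------------------------------------------------------- #
# elevational occupancy / turnover
# --------------------------------------------------------------------------- #


def level_occupancy(
    p: Partition, meta: pd.DataFrame, exclude_rare: bool = False
) -> Dict[int, float]:
    """Percentage of groups found at exactly 1, 2, ... elevation levels.

    ``exclude_rare`` first removes groups with one or two specimens, which
    can trivially occur at only one or two levels.
    """
    level_of = dict(zip(meta["specimen_id"], meta["level"]))
    missing = [s for s in p.specimens if s not in level_of]
    if missing:
        raise ValueError(f"specimens without a level: {sorted(missing)[:10]}")
    n_levels_total = meta["level"].nunique()
    counts: Dict[int, int] = {k: 0 for k in range(1, n_levels_total + 1)}
    n_groups = 0
    for block in p.blocks:
        if exclude_rare and len(block) <= 2:
            continue
        n_groups += 1
        occ = len({level_of[s] for s in block})
        counts[occ] = counts.get(occ, 0) + 1
    if n_groups == 0:
        raise ValueError("no groups left after excluding rare groups")
    return {k: 100.0 * v / n_groups for k, v in sorted(counts.items())}
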