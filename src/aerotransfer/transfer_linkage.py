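"""Matched home-stable pair ranking: a rank statistic for bacterial transfer.

Each farmer links one home sample to one stable sample through a shared farm
id.  If airborne bacteria move between the two buildings, the community
distance between a home and its *own* stable should be smaller than the
distances from that home to other farmers' stables.  The statistic ranks
every matched home-stable distance among the non-matching alternatives; a
rank of 1 signals substantial transfer, and the cohort-level fraction of
rank-1 pairs is compared against the null of random home-stable association
by permuting the matching.

Two ranking universes are provided:

``row_wise`` (default)
    the matched distance is ranked among that home's distances to *all*
    stables; under no transfer the rank is uniform on 1..n_stables, so the
    expected rank-1 fraction is 1/n_stables.

``global``
    the matched distance is ranked within the pooled set of all
    non-matching home-stable distances plus itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .tables_io import (
    HOME_ENVIRONMENT,
    STABLE_ENVIRONMENT,
    Metadata,
    ValidationError,
    derive_seed,
)

__all__ = [
    "PairRanking",
    "TransferSummary",
    "matched_pair_distances",
    "rank_matched_pairs",
    "transfer_test",
    "ranking_frame",
]

RANKING_MODES = ("row_wise", "global")


@dataclass(frozen=True)
class PairRanking:
    """Rank of one matched home-stable distance among its alternatives.

    Ties contribute 1/2 to the rank count, so ``rank`` can be half-integer;
    ``is_rank_one`` holds exactly when rank == 1.
    """

    farm_id: str
    home_sample_id: str
    stable_sample_id: str
    matched_distance: float
    rank: float
    n_alternatives: int
    is_rank_one: bool


@dataclass(frozen=True)
class TransferSummary:
    """Cohort-level rank-1 fraction with its permutation null p-value.

    ``null_expectation`` is the mean over pairs of ``1/(n_alternatives+1)``
    (exact for row-wise ranking under no transfer).  ``binomial_p`` is the
    closed-form binomial tail, reported when every pair shares the same
    number of alternatives (and None otherwise).
    """

    n_pairs: int
    n_rank_one: int
    fraction_rank_one: float
    null_expectation: float
    p_value: float
    binomial_p: float | None
    ranking_mode: str
    n_null_draws: int
    seed: int


def matched_pair_distances(
    d: DistanceMatrix, meta: Metadata, livestock: str
) -> tuple[pd.DataFrame, dict[str, tuple[str, str]], dict[str, list[str]]]:
    """Home x stable distance sub-matrix and farm matching for one livestock type.

    Rows are the homes of farms that have both a home and a stable sample
    (the matched homes); columns are *all* stables of the livestock type, so
    unmatched stables still serve as ranking alternatives.  Homes without a
    stable counterpart (and vice versa) are reported in the log.  When a farm
    has two samples of one environment (seasonal repeats), the first in
    metadata order is used and the repeat is logged.

    Returns ``(sub_matrix, matching, log)`` with
    ``matching: farm_id -> (home_sample_id, stable_sample_id)``.
    """
    if livestock not in HOME_ENVIRONMENT:
        raise ValidationError(
            f"unknown livestock {livestock!r}; expected one of {sorted(HOME_ENVIRONMENT)}"
        )
    ids = set(d.ids)
    home_env = HOME_ENVIRONMENT[livestock]
    stable_env = STABLE_ENVIRONMENT[livestock]
    homes_by_farm: dict[str, list[str]] = {}
    stables_by_farm: dict[str, list[str]] = {}
    all_stables: list[str] = []
    log: dict[str, list[str]] = {
        "unmatched_homes": [],
        "unmatched_stables": [],
        "duplicate_farm_samples": [],
    }
    for rec in meta.records:
        if rec.sample_id not in ids:
            continue
        if rec.environment == home_env:
            if rec.farm_id:
                homes_by_farm.setdefault(rec.farm_id, []).append(rec.sample_id)
            else:
                log["unmatched_homes"].append(rec.sample_id)
        elif rec.environment == stable_env:
            all_stables.append(rec.sample_id)
            if rec.farm_id:
                stables_by_farm.setdefault(rec.farm_id, []).append(rec.sample_id)

    matching: dict[str, tuple[str, str]] = {}
    for farm in sorted(set(homes_by_farm) | set(stables_by_farm)):
        homes = homes_by_farm.get(farm, [])
        stables = stables_by_farm.get(farm, [])
        for extra in homes[1:] + stables[1:]:
            log["duplicate_farm_samples"].append(extra)
        if homes and stables:
            matching[farm] = (homes[0], stables[0])
        elif homes:
            log["unmatched_homes"].extend(homes[:1])
        else:
            log["unmatched_stables"].extend(stables[:1])
    if not matching:
        raise ValidationError(
            f"no matched {livestock} farms (shared farm_id with both home and stable)"
        )
    matched_homes = [matching[f][0] for f in matching]
    full = d.to_data_frame()
    sub = full.loc[matched_homes, all_stables]
    return sub, matching, log


def rank_matched_pairs(
    sub_matrix: pd.DataFrame,
    matching: dict[str, tuple[str, str]],
    mode: str = "row_wise",
) -> list[PairRanking]:
    """Rank every matched distance among its non-matching alternatives.

    row_wise: ``rank = 1 + #{other stables closer to this home}`` (ties
    count 1/2).  global: the matched distance is ranked within all
    non-matching entries of the sub-matrix plus itself.
    """
    if mode not in RANKING_MODES:
        raise ValueError(f"unknown ranking mode {mode!r}")
    values = sub_matrix.to_numpy(dtype=float)
    home_pos = {h: i for i, h in enumerate(sub_matrix.index)}
    stable_pos = {s: j for j, s in enumerate(sub_matrix.columns)}
    matched_cells = {
        farm: (home_pos[h], stable_pos[s]) for farm, (h, s) in matching.items()
    }
    if mode == "global":
        matched_mask = np.zeros(values.shape, dtype=bool)
        for i, j in matched_cells.values():
            matched_mask[i, j] = True
        pool = values[~matched_mask]
    rankings = []
    for farm in sorted(matching):
        h, s = matching[farm]
        i, j = matched_cells[farm]
        d0 = values[i, j]
        if mode == "row_wise":
            row = np.delete(values[i], j)
            rank = 1.0 + np.sum(row < d0) + 0.5 * np.sum(row == d0)
            n_alt = row.size
        else:
            rank = 1.0 + np.sum(pool < d0) + 0.5 * np.sum(pool == d0)
            n_alt = pool.size
        rankings.append(
            PairRanking(
                farm_id=farm,
                home_sample_id=h,
                stable_sample_id=s,
                matched_distance=float(d0),
                rank=float(rank),
                n_alternatives=int(n_alt),
                is_rank_one=bool(rank == 1.0),
            )
        )
    return rankings


def ranking_frame(rankings: list[PairRanking]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "farm_id": [r.farm_id for r in rankings],
            "home_sample_id": [r.home_sample_id for r in rankings],
            "stable_sample_id": [r.stable_sample_id for r in rankings],
            "matched_distance": [r.matched_distance for r in rankings],
            "rank": [r.rank for r in rankings],
            "n_alternatives": [r.n_alternatives for r in rankings],
            "is_rank_one": [r.is_rank_one for r in rankings],
        }
    )


def transfer_test(
    sub_matrix: pd.DataFrame,
    matching: dict[str, tuple[str, str]],
    mode: str = "row_wise",
    n_null_draws: int = 999,
    seed: int = 0,
) -> tuple[TransferSummary, list[PairRanking]]:
    """Test the cohort rank-1 fraction against random home-stable association.

    The null re-assigns the matched stables to the matched homes by a random
    permutation ``n_null_draws`` times and re-ranks;
    ``p = (1 + #{null fraction >= observed}) / (1 + n_null_draws)``.  When
    every pair has the same number of alternatives the closed-form binomial
    tail ``P(X >= n_rank_one), X ~ Bin(n_pairs, 1/(n_alternatives+1))`` is
    reported alongside.
    """
    if n_null_draws < 1:
        raise ValueError(f"n_null_draws must be >= 1, got {n_null_draws}")
    rankings = rank_matched_pairs(sub_matrix, matching, mode=mode)
    if not rankings:
        raise ValidationError("no matched pairs to test")
    n_pairs = len(rankings)
    n_rank_one = sum(r.is_rank_one for r in rankings)
    frac = n_rank_one / n_pairs
    null_expectation = float(np.mean([1.0 / (r.n_alternatives + 1) for r in rankings]))

    farms = sorted(matching)
    stables = [matching[f][1] for f in farms]
    rng = np.random.default_rng(derive_seed(seed, "transfer_null", mode))
    hits = 0
    for _ in range(n_null_draws):
        perm = rng.permutation(len(farms))
        null_matching = {
            farms[k]: (matching[farms[k]][0], stables[perm[k]])
            for k in range(len(farms))
        }
        null_rankings = rank_matched_pairs(sub_matrix, null_matching, mode=mode)
        null_frac = sum(r.is_rank_one for r in null_rankings) / n_pairs
        if null_frac >= frac - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_null_draws)

    n_alts = {r.n_alternatives for r in rankings}
    binom_p: float | None = None
    if len(n_alts) == 1:
        k = n_alts.pop()
        binom_p = float(stats.binom.sf(n_rank_one - 1, n_pairs, 1.0 / (k + 1)))

    summary = TransferSummary(
        n_pairs=n_pairs,
        n_rank_one=n_rank_one,
        fraction_rank_one=frac,
        null_expectation=null_expectation,
        p_value=p,
        binomial_p=binom_p,
        ranking_mode=mode,
        n_null_draws=n_null_draws,
        seed=seed,
    )
    return summary, rankings
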