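"""Within-sample diversity (observed richness, Shannon index) and group tests.

Richness and Shannon diversity are computed per sample on the
depth-equalized table; environment groups are compared with the
Wilcoxon/Mann-Whitney rank-sum test (exact for small untied samples,
otherwise the tie- and continuity-corrected normal approximation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import FeatureTable, Metadata, ValidationError

__all__ = [
    "AlphaRecord",
    "alpha_metrics",
    "alpha_frame",
    "rank_sum_test",
    "compare_groups_alpha",
]

#: n1 + n2 at or below which the exact rank-sum null is enumerated (no ties).
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class AlphaRecord:
    """Observed richness and Shannon entropy (natural log) of one sample."""

    sample_id: str
    observed: int
    shannon: float


def alpha_metrics(table: FeatureTable, base: float = np.e) -> list[AlphaRecord]:
    """Observed richness and Shannon index for every sample.

    observed = number of features with count > 0; shannon = -sum p ln p over
    the sample's proportions (0 ln 0 := 0), in units of ``ln base``
    (natural log by default).
    """
    sums = table.sample_sums()
    zero = [s for s, t in zip(table.sample_ids, sums) if t == 0]
    if zero:
        raise ValidationError(f"all-zero samples: {zero}")
    records = []
    log_base = np.log(base)
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        nz = col[col > 0].astype(float)
        p = nz / nz.sum()
        shannon = float(-(p * np.log(p)).sum() / log_base)
        records.append(AlphaRecord(sample_id=sid, observed=int(len(nz)), shannon=shannon))
    return records


def alpha_frame(records: Sequence[AlphaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "observed": [r.observed for r in records],
            "shannon": [r.shannon for r in records],
        }
    )


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
) -> tuple[float, float]:
    """Mann-Whitney U test with average ranks for ties.

    Exact p by enumeration when the pooled size is at most
    ``EXACT_RANKSUM_MAX_N`` and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction.

    Returns ``(U, p_value)`` where U counts pairs in which an ``x`` value
    exceeds a ``y`` value (ties half).
    """
    alt_map = {"two_sided": "two-sided", "less": "less", "greater": "greater"}
    if alternative not in alt_map:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and (x.size + y.size) <= EXACT_RANKSUM_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alt_map[alternative], method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def compare_groups_alpha(
    records: Sequence[AlphaRecord],
    meta: Metadata,
    pairs: Sequence[tuple[str, str]],
    stratify_by_season: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of richness and Shannon between environments.

    One row per (environment pair, metric[, season stratum]) with group
    medians, sizes, U, and p.  ``stratify_by_season`` adds per-season rows
    (for contrasts such as summer-vs-winter richness within one
    environment, pass the same environment twice and stratify).  ``holm``
    optionally applies a Holm step-down correction over the panel; raw
    pairwise p-values are the default presentation.
    """
    by_sample = {r.sample_id: r for r in records}
    rows = []

    def _values(env: str, season: str | None) -> tuple[list[float], list[float]]:
        ids = [
            s
            for s in meta.group_ids(env)
            if s in by_sample and (season is None or meta[s].season == season)
        ]
        return (
            [float(by_sample[s].observed) for s in ids],
            [by_sample[s].shannon for s in ids],
        )

    strata: list[str | None] = [None]
    if stratify_by_season:
        strata = ["summer", "winter"]
    for env_a, env_b in pairs:
        for season in strata:
            obs_a, sh_a = _values(env_a, season)
            obs_b, sh_b = _values(env_b, season)
            for metric, a, b in (("observed", obs_a, obs_b), ("shannon", sh_a, sh_b)):
                if not a or not b:
                    raise ValidationError(
                        f"empty group in comparison {env_a} vs {env_b}"
                        + (f" (season {season})" if season else "")
                    )
                u, p = rank_sum_test(a, b)
                rows.append(
                    {
                        "group_a": env_a,
                        "group_b": env_b,
                        "season": season or "all",
                        "metric": metric,
                        "n_a": len(a),
                        "n_b": len(b),
                        "median_a": float(np.median(a)),
                        "median_b": float(np.median(b)),
                        "U": u,
                        "p_value": p,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "group_a",
            "group_b",
            "season",
            "metric",
            "n_a",
            "n_b",
            "median_a",
            "median_b",
            "U",
            "p_value",
        ],
    )
    if holm and len(df):
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * df["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        df["p_holm"] = adj
    return df
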