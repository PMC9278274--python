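"""Depth equalization, negative-control decontamination, taxonomic aggregation.

Sequencing depth varies by orders of magnitude between dust samples, and
richness estimates inflate with depth, so all samples are first subsampled
without replacement to a common depth (a multivariate hypergeometric draw per
sample).  Reagent and handling contaminants are then identified by contrasting
each feature's presence/absence prevalence in true samples against negative
(unexposed-collector / extraction-blank) controls, and removed.  Finally,
features can be aggregated to any taxonomic rank and summarized as group-mean
relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import (
    RANKS,
    FeatureTable,
    Metadata,
    TaxonomyTable,
    ValidationError,
    derive_seed,
)

__all__ = [
    "subsample_to_depth",
    "ContaminantReport",
    "prevalence_contaminant_scores",
    "remove_contaminants",
    "contaminant_frame",
    "aggregate_taxa",
    "group_mean_relative_abundance",
]


def subsample_to_depth(
    table: FeatureTable, depth: int, seed: int
) -> tuple[FeatureTable, list[str]]:
    """Rarefy every sample to exactly ``depth`` reads without replacement.

    Each retained sample's reads are a multivariate hypergeometric draw from
    its original reads, so per-feature drawn counts never exceed the
    originals and expectations are proportional to the original composition.
    Samples with fewer than ``depth`` total reads are dropped and listed.

    The random stream for each sample is derived from ``(seed, sample_id)``,
    so results are independent of sample order.

    Returns ``(subsampled_table, dropped_sample_ids)``.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    sums = table.sample_sums()
    keep_idx = [i for i, t in enumerate(sums) if t >= depth]
    dropped = [table.sample_ids[i] for i, t in enumerate(sums) if t < depth]
    new_counts = np.empty((table.n_features, len(keep_idx)), dtype=np.int64)
    for out_j, j in enumerate(keep_idx):
        sid = table.sample_ids[j]
        col = table.counts[:, j]
        if sums[j] == depth:
            new_counts[:, out_j] = col
            continue
        rng = np.random.default_rng(derive_seed(seed, "subsample", sid))
        new_counts[:, out_j] = rng.multivariate_hypergeometric(col, depth)
    sub = FeatureTable(
        new_counts, list(table.feature_ids), [table.sample_ids[j] for j in keep_idx]
    )
    return sub, dropped


# ---------------------------------------------------------------------------
# Prevalence-based decontamination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContaminantReport:
    """Prevalence contrast of one feature between negative controls and true samples.

    ``score`` is the two-sided Fisher exact probability of the 2x2
    presence/absence table; a feature is called a contaminant when the score
    is at or below the threshold *and* it is relatively more prevalent in
    controls than in true samples (direction guard).
    """

    feature_id: str
    prevalence_in_controls: float
    prevalence_in_samples: float
    score: float
    is_contaminant: bool


def prevalence_contaminant_scores(
    table: FeatureTable,
    meta: Metadata,
    threshold: float = 0.1,
    presence_min: int = 1,
) -> list[ContaminantReport]:
    """Score every feature by its control-vs-sample presence/absence contrast.

    A feature is "present" in a sample when it has at least ``presence_min``
    reads.  For each feature the 2x2 contingency (present/absent x
    control/true sample) is tested with the two-sided Fisher exact test;
    small scores with control-enriched direction flag contaminants.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if presence_min < 1:
        raise ValueError(f"presence_min must be >= 1, got {presence_min}")
    ctrl_ids = [s for s in table.sample_ids if s in meta and meta[s].is_control]
    true_ids = [s for s in table.sample_ids if s in meta and not meta[s].is_control]
    if not ctrl_ids:
        raise ValidationError(
            "decontamination requires negative-control samples; none found"
        )
    if not true_ids:
        raise ValidationError("decontamination requires at least one true sample")
    present = table.counts >= presence_min
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    ctrl = present[:, [idx[s] for s in ctrl_ids]]
    true = present[:, [idx[s] for s in true_ids]]
    n_ctrl, n_true = len(ctrl_ids), len(true_ids)
    ctrl_hits = ctrl.sum(axis=1)
    true_hits = true.sum(axis=1)

    reports = []
    cache: dict[tuple[int, int], float] = {}
    for i, fid in enumerate(table.feature_ids):
        a, b = int(ctrl_hits[i]), int(true_hits[i])
        key = (a, b)
        if key not in cache:
            tab = [[a, n_ctrl - a], [b, n_true - b]]
            cache[key] = float(stats.fisher_exact(tab, alternative="two-sided")[1])
        score = cache[key]
        prev_c = a / n_ctrl
        prev_t = b / n_true
        flag = score <= threshold and prev_c >= prev_t and a > 0
        reports.append(
            ContaminantReport(
                feature_id=fid,
                prevalence_in_controls=prev_c,
                prevalence_in_samples=prev_t,
                score=score,
                is_contaminant=flag,
            )
        )
    return reports


def contaminant_frame(reports: list[ContaminantReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in reports],
            "prevalence_in_controls": [r.prevalence_in_controls for r in reports],
            "prevalence_in_samples": [r.prevalence_in_samples for r in reports],
            "score": [r.score for r in reports],
            "is_contaminant": [r.is_contaminant for r in reports],
        }
    )


def remove_contaminants(
    table: FeatureTable, reports: list[ContaminantReport]
) -> FeatureTable:
    """Drop every feature flagged as a contaminant."""
    flagged = [r.feature_id for r in reports if r.is_contaminant]
    return table.drop_features(flagged)


# ---------------------------------------------------------------------------
# Taxonomic aggregation and abundance summaries
# ---------------------------------------------------------------------------


def aggregate_taxa(
    table: FeatureTable, taxonomy: TaxonomyTable, level: str
) -> FeatureTable:
    """Sum feature counts into distinct taxa at a rank; column sums conserved.

    Features lacking a name at the rank fall into an
    "Unclassified <nearest named parent>" bucket.
    """
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}; expected one of {RANKS}")
    labels = [taxonomy.label_at(fid, level) for fid in table.feature_ids]
    df = table.to_dataframe()
    # preserve first-appearance order of taxa
    agg = df.groupby(labels, sort=False).sum()
    return FeatureTable.from_dataframe(agg)


def group_mean_relative_abundance(
    table: FeatureTable,
    meta: Metadata,
    min_mean_abundance: float = 0.0001,
) -> pd.DataFrame:
    """Taxon x environment matrix of mean relative abundances, in percent.

    Per sample, counts are closed to proportions; per environment the
    proportions are averaged over samples and expressed in percent.  Taxa
    whose overall (all-sample) mean proportion is below
    ``min_mean_abundance`` are pooled into an "Other" row.
    """
    props = table.relative_abundance()
    df = pd.DataFrame(props, index=table.feature_ids, columns=table.sample_ids)
    envs = []
    for s in table.sample_ids:
        if s not in meta:
            raise ValidationError(f"sample {s!r} missing from metadata")
        envs.append(meta.environment_of(s))
    group_means = df.T.groupby(envs, sort=False).mean().T  # taxa x environments
    for env in group_means.columns:
        if (np.asarray(envs) == env).sum() == 0:  # pragma: no cover - defensive
            raise ValidationError(f"empty environment group {env!r}")
    overall = df.mean(axis=1)
    minor = overall < min_mean_abundance
    if minor.any():
        pooled = group_means.loc[minor].sum(axis=0)
        group_means = group_means.loc[~minor]
        group_means.loc["Other"] = pooled
    return group_means * 100.0
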