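"""Compositional beta diversity: CLR, Aitchison distances, PCoA, ANOSIM.

Count compositions carry only relative information, so between-sample
structure is analysed in Aitchison geometry: counts (plus a small
pseudocount for zeros) are centered-log-ratio transformed and compared with
Euclidean distance.  The resulting distance matrix is ordinated by principal
coordinates analysis and group separation is quantified by the rank-based
analysis of similarity (ANOSIM) with permutation p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .tables_io import FeatureTable, Metadata, ValidationError

__all__ = [
    "clr_array",
    "clr_transform",
    "aitchison_distance",
    "Ordination",
    "pcoa",
    "AnosimResult",
    "anosim",
    "pairwise_anosim",
]

#: Enumerate the exact permutation null when the number of distinct label
#: orderings is at most this; otherwise sample random permutations.
EXACT_ANOSIM_MAX_PERMUTATIONS = 20_000


def clr_array(parts: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Centered log-ratio of compositions (rows): ``ln x_i - mean_j ln x_j``.

    Accepts any positive parts (counts, proportions); scale per row is
    irrelevant.  Each output row sums to zero.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be non-negative, got {pseudocount}")
    x = np.atleast_2d(np.asarray(parts, dtype=float)) + pseudocount
    if np.any(x <= 0):
        raise ValueError("non-positive parts require a positive pseudocount")
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def clr_transform(table: FeatureTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform of a count table, samples in rows.

    Per sample, ``clr_i = ln(c_i + pseudocount) - mean_j ln(c_j + pseudocount)``.
    A positive pseudocount handles the zeros ubiquitous in subsampled count
    tables; zero is allowed only when every count is already positive.
    Each returned row sums to zero.
    """
    clr = clr_array(table.counts.T, pseudocount)
    return pd.DataFrame(clr, index=list(table.sample_ids), columns=list(table.feature_ids))


def aitchison_distance(clr_matrix: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between CLR rows (the Aitchison metric)."""
    values = np.asarray(clr_matrix, dtype=float)
    if values.ndim != 2:
        raise ValueError("clr matrix must be 2-D (samples x features)")
    sq = np.sum(values**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * values @ values.T
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    ids = [str(i) for i in clr_matrix.index]
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# Principal coordinates analysis
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    """PCoA embedding: sample coordinates, eigenvalues, variance fractions.

    Eigenvalues are sorted non-increasing; coordinates span the positive
    eigenvalues only (negative ones, which cannot arise for exactly
    Euclidean inputs like Aitchison matrices beyond round-off, are reported
    but their axes omitted).  ``proportion_explained`` is computed over the
    positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix, n_axes: int = 3) -> Ordination:
    """Classical metric scaling by Gower double-centering and eigendecomposition.

    ``B = -1/2 J D^2 J`` with ``J`` the centering projector; coordinates are
    eigenvectors scaled by the square root of their (positive) eigenvalues.
    """
    if n_axes < 2:
        raise ValueError(f"n_axes must be >= 2, got {n_axes}")
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    d2 = dm**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 1e-12
    pos_sum = eigvals[pos].sum()
    if pos_sum <= 0:
        coords = np.zeros((n, 0))
        prop = np.zeros(0)
    else:
        keep = min(n_axes, int(pos.sum()))
        coords = eigvecs[:, :keep] * np.sqrt(eigvals[:keep])
        prop = eigvals[:keep] / pos_sum
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM statistic and permutation p-value for one grouping.

    R in [-1, 1]: 1 means every between-group distance ranks above every
    within-group distance; 0 is the null expectation.
    """

    R: float
    p_value: float
    n_permutations: int
    seed: int
    method: str
    group_sizes: tuple[int, ...]


def _anosim_r(rank_square: np.ndarray, labels: np.ndarray, denom: float) -> float:
    within = labels[:, None] == labels[None, :]
    iu = np.triu_indices(labels.size, k=1)
    w = within[iu]
    r = rank_square[iu]
    return float((r[~w].mean() - r[w].mean()) / denom)


def anosim(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "auto",
) -> AnosimResult:
    """Analysis of similarity on a distance matrix.

    All pairwise distances are ranked (average ranks on ties) and
    ``R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)``.
    Significance comes from permuting the group labels with fixed group
    sizes: ``p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations)`` in
    ``method="permutation"``, or the exact fraction over all distinct label
    orderings in ``method="exact"``.  ``"auto"`` enumerates exactly when
    feasible and samples otherwise.
    """
    labels = np.asarray([str(g) for g in groups])
    n = len(labels)
    if n != d.shape[0]:
        raise ValueError(f"{n} labels for {d.shape[0]} samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        small = [u for u, c in zip(uniq, counts) if c < 2]
        raise ValidationError(f"groups with fewer than 2 samples: {small}")
    if method not in ("auto", "exact", "permutation"):
        raise ValueError(f"unknown method {method!r}")

    condensed = squareform(np.asarray(d.data, dtype=float), checks=False)
    rank_square = squareform(rankdata(condensed))
    denom = n * (n - 1) / 4.0
    r_obs = _anosim_r(rank_square, labels, denom)

    n_distinct = _multiset_permutation_count(counts)
    use_exact = method == "exact" or (
        method == "auto" and n_distinct <= EXACT_ANOSIM_MAX_PERMUTATIONS
    )
    tol = 1e-12
    if use_exact:
        hits = 0
        total = 0
        for perm in _distinct_label_orderings(uniq, counts):
            total += 1
            if _anosim_r(rank_square, perm, denom) >= r_obs - tol:
                hits += 1
        p = hits / total
        return AnosimResult(r_obs, p, total, seed, "exact", tuple(int(c) for c in counts))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(rank_square, perm, denom) >= r_obs - tol:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(
        r_obs, p, n_permutations, seed, "permutation", tuple(int(c) for c in counts)
    )


def _distinct_label_orderings(uniq: np.ndarray, counts: np.ndarray):
    """Yield every distinct assignment of the label multiset to positions."""
    n = int(counts.sum())
    out = np.empty(n, dtype=object)

    def rec(avail: tuple[int, ...], gi: int):
        if gi == len(uniq) - 1:
            for p in avail:
                out[p] = uniq[gi]
            yield out
            return
        for chosen in itertools.combinations(avail, int(counts[gi])):
            chosen_set = set(chosen)
            rest = tuple(p for p in avail if p not in chosen_set)
            for p in chosen:
                out[p] = uniq[gi]
            yield from rec(rest, gi + 1)

    yield from rec(tuple(range(n)), 0)


def _multiset_permutation_count(counts: np.ndarray) -> int:
    from math import factorial

    total = factorial(int(counts.sum()))
    for c in counts:
        total //= factorial(int(c))
    return total


def pairwise_anosim(
    d: DistanceMatrix,
    meta: Metadata,
    pairs: Sequence[tuple[str, str]],
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """ANOSIM for each environment pair on the matching sub-matrix.

    Rows are sorted by R descending (strongest separation first).
    """
    ids = set(d.ids)
    rows = []
    for env_a, env_b in pairs:
        ids_a = [s for s in meta.group_ids(env_a) if s in ids]
        ids_b = [s for s in meta.group_ids(env_b) if s in ids]
        sub_ids = ids_a + ids_b
        sub = d.filter(sub_ids)
        labels = [env_a] * len(ids_a) + [env_b] * len(ids_b)
        res = anosim(
            sub,
            labels,
            n_permutations=n_permutations,
            seed=seed,
            method="permutation",
        )
        rows.append(
            {
                "group_a": env_a,
                "group_b": env_b,
                "n_a": len(ids_a),
                "n_b": len(ids_b),
                "R": res.R,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "n_a", "n_b", "R", "p_value", "n_permutations"],
    )
    return df.sort_values("R", ascending=False, kind="mergesort").reset_index(drop=True)
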