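"""Split-half subject identifiability: the identifiability matrix and Iself/Iothers/Idiff.

For a group of s subjects the identifiability matrix A is s x s, with
``a[i, j]`` the Pearson correlation between the second-half edge vector of
subject i (rows) and the first-half edge vector of subject j (columns),
restricted to an edge selection X. From A:

* ``Iself_i  = a[i, i]`` — temporal stability of subject i's fingerprint;
* ``Iothers_i = (1 / (2(s-1))) * sum_{j != i} (a[i, j] + a[j, i])`` —
  similarity of subject i to the other subjects of the same condition;
* ``Idiff_i = Iself_i - Iothers_i`` — within-group identifiability.

Iothers always uses within-condition pairs only; matrices mixing the two
conditions are produced solely for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_fc import EdgeIndex, FCPair, build_edge_index, vectorize_edges


@dataclass
class IdentifiabilityMatrix:
    """Cross split-half correlation matrix of one condition's subjects."""

    condition: str
    a: np.ndarray  # s x s; rows = second half, columns = first half
    subject_ids: list[str]
    selection_id: str = "all-edges"

    @property
    def n_subjects(self) -> int:
        return self.a.shape[0]


@dataclass
class FingerprintMetrics:
    condition: str
    subject_ids: list[str]
    iself: np.ndarray
    iothers: np.ndarray
    idiff: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "condition": self.condition,
                "iself": self.iself,
                "iothers": self.iothers,
                "idiff": self.idiff,
            }
        )


def _edge_vectors(pairs: Sequence[FCPair], idx: EdgeIndex) -> tuple[np.ndarray, np.ndarray]:
    """(s x E) first-half and second-half edge-vector stacks."""
    first = np.stack([vectorize_edges(p.first, idx) for p in pairs])
    second = np.stack([vectorize_edges(p.second, idx) for p in pairs])
    return first, second


def _standardize_rows(x: np.ndarray, what: str) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance {what} edge vector; correlation undefined")
    return (x - mu) / sd


def identifiability_matrix(
    pairs: Sequence[FCPair],
    idx: EdgeIndex | None = None,
    selection: np.ndarray | None = None,
    selection_id: str = "all-edges",
) -> IdentifiabilityMatrix:
    """Cross-correlate second-half (rows) with first-half (columns) edge vectors.

    Parameters
    ----------
    pairs
        Split-half FCs of the subjects of one condition.
    selection
        Optional edge-id subset X (``None`` means all edges). Needs at least
        3 edges for the Pearson correlation to be meaningful.
    """
    if not pairs:
        raise ValueError("no subjects")
    conditions = {p.condition for p in pairs}
    if len(conditions) != 1:
        raise ValueError(f"subjects span multiple conditions: {sorted(conditions)}")
    if idx is None:
        idx = build_edge_index(pairs[0].first.n_regions)
    first, second = _edge_vectors(pairs, idx)
    if selection is not None:
        selection = np.asarray(selection, dtype=int)
        if selection.size < 3:
            raise ValueError("edge selection must contain at least 3 edges")
        first = first[:, selection]
        second = second[:, selection]
    m = first.shape[1]
    z1 = _standardize_rows(first, "first-half")
    z2 = _standardize_rows(second, "second-half")
    a = (z2 @ z1.T) / m
    np.clip(a, -1.0, 1.0, out=a)
    return IdentifiabilityMatrix(
        condition=pairs[0].condition,
        a=a,
        subject_ids=[p.subject_id for p in pairs],
        selection_id=selection_id,
    )


def fingerprint_metrics(A: IdentifiabilityMatrix) -> FingerprintMetrics:
    """Iself, Iothers, and Idiff for every subject of one condition."""
    a = A.a
    s = a.shape[0]
    if s < 2:
        raise ValueError("need at least 2 subjects for Iothers")
    iself = np.diag(a).copy()
    iothers = (a.sum(axis=1) + a.sum(axis=0) - 2.0 * iself) / (2.0 * (s - 1))
    return FingerprintMetrics(
        condition=A.condition,
        subject_ids=A.subject_ids,
        iself=iself,
        iothers=iothers,
        idiff=iself - iothers,
    )


def combined_display_matrix(
    pairs_by_condition: Mapping[str, Sequence[FCPair]],
    idx: EdgeIndex | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """All-subject cross split-half correlation matrix, conditions blocked together.

    For display only — fingerprint metrics are always computed per condition.
    Returns (matrix, subject_ids, condition per subject).
    """
    all_pairs: list[FCPair] = []
    for cond in sorted(pairs_by_condition):
        all_pairs.extend(pairs_by_condition[cond])
    if idx is None:
        idx = build_edge_index(all_pairs[0].first.n_regions)
    first, second = _edge_vectors(all_pairs, idx)
    z1 = _standardize_rows(first, "first-half")
    z2 = _standardize_rows(second, "second-half")
    a = (z2 @ z1.T) / first.shape[1]
    np.clip(a, -1.0, 1.0, out=a)
    return a, [p.subject_id for p in all_pairs], [p.condition for p in all_pairs]


def default_curve_grid(n_edges: int, step: int = 50) -> np.ndarray:
    """Edge-count grid {step, 2*step, ...} ending exactly at n_edges."""
    grid = np.arange(step, n_edges + 1, step)
    if grid.size == 0 or grid[-1] != n_edges:
        grid = np.append(grid, n_edges)
    return grid


def identifiability_curve(
    pairs_by_condition: Mapping[str, Sequence[FCPair]],
    icc_ranking: np.ndarray,
    n_grid: np.ndarray | Sequence[int],
    idx: EdgeIndex | None = None,
    ranking_source: str = "",
) -> pd.DataFrame:
    """Group mean and standard error of Idiff/Iself/Iothers over top-n edge subsets.

    ``icc_ranking`` is a full edge ordering (best first), typically the
    descending-ICC order of one condition; metrics at each grid point n are
    computed for BOTH conditions on the top-n ranked edges. Standard error is
    sample SD / sqrt(s).

    Returns a long-format frame with columns
    ``condition, n, metric, mean, sem, ranking_source``.
    """
    some_pairs = next(iter(pairs_by_condition.values()))
    if idx is None:
        idx = build_edge_index(some_pairs[0].first.n_regions)
    icc_ranking = np.asarray(icc_ranking, dtype=int)
    if icc_ranking.size != idx.n_edges or len(np.unique(icc_ranking)) != idx.n_edges:
        raise ValueError("icc_ranking must be a permutation of all edge ids")
    n_grid = np.asarray(n_grid, dtype=int)
    if np.any(np.diff(n_grid) <= 0):
        raise ValueError("n_grid must be strictly increasing")
    if n_grid[0] < 3 or n_grid[-1] > idx.n_edges:
        raise ValueError("n_grid must lie within [3, n_edges]")

    # Precompute full edge-vector stacks once per condition.
    stacks = {
        cond: _edge_vectors(pairs, idx) for cond, pairs in pairs_by_condition.items()
    }
    rows = []
    for n in n_grid:
        sel = icc_ranking[:n]
        for cond, (first, second) in stacks.items():
            f = first[:, sel]
            sc = second[:, sel]
            z1 = _standardize_rows(f, "first-half")
            z2 = _standardize_rows(sc, "second-half")
            a = np.clip((z2 @ z1.T) / n, -1.0, 1.0)
            s = a.shape[0]
            iself = np.diag(a)
            iothers = (a.sum(axis=1) + a.sum(axis=0) - 2.0 * iself) / (2.0 * (s - 1))
            idiff = iself - iothers
            for metric, vals in (("idiff", idiff), ("iself", iself), ("iothers", iothers)):
                rows.append(
                    {
                        "condition": cond,
                        "n": int(n),
                        "metric": metric,
                        "mean": float(vals.mean()),
                        "sem": float(vals.std(ddof=1) / np.sqrt(s)),
                        "ranking_source": ranking_source,
                    }
                )
    return pd.DataFrame(rows)
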