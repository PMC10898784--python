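"""Edgewise idiosyncrasy maps: class-1 intraclass correlation across FC halves.

An edge is *idiosyncratic* when its value differs strongly between subjects
while staying stable across the two temporal halves of the same subject's
scan. With two measurements per subject (first-half and second-half FC
value), the class-1 intraclass correlation is

    ICC = (MSR - MSW) / (MSR + MSW)

where MSR = 2 * var(mu) is twice the across-subject sample variance of the
per-subject means mu_i, and MSW is the mean across subjects of the
per-subject within-pair variances sigma_i = (x_first - x_second)^2 / 2.
These divisor conventions make the formula coincide exactly with the
classical one-way random-effects ICC(1,1) at k = 2 raters.

Regional idiosyncrasy is summarized by *ICC strength*: the sum of the
(unthresholded) ICC values of all edges incident to a region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_fc import (
    EdgeIndex,
    FCPair,
    Parcellation,
    RSN_LABELS,
    build_edge_index,
    rsn_pair_label,
    rsn_pair_list,
    vectorize_edges,
)
from .stats import bh_fdr, t_test


@dataclass
class ICCResult:
    """Per-edge class-1 ICC of one condition, with its ANOVA ingredients."""

    condition: str
    icc: np.ndarray          # (n_edges,), in [-1, 1]
    msr: np.ndarray          # between-subject mean square, per edge
    msw: np.ndarray          # within-subject mean square, per edge
    mu: np.ndarray = field(repr=False)      # (s, n_edges) per-subject across-half means
    sigma: np.ndarray = field(repr=False)   # (s, n_edges) per-subject within-pair variances
    degenerate: np.ndarray = field(repr=False)  # mask of MSR+MSW == 0 edges (ICC set to 0)

    @property
    def n_edges(self) -> int:
        return self.icc.size

    def ranking(self) -> np.ndarray:
        """All edge ids ordered by descending ICC; ties broken by ascending edge id."""
        order = np.lexsort((np.arange(self.n_edges), -self.icc))
        return order


@dataclass
class ICCStrength:
    """Per-region sum of unthresholded ICC over incident edges."""

    condition: str
    strength: np.ndarray  # (n_regions,)


def icc_from_measurements(first: np.ndarray, second: np.ndarray,
                          condition: str = "") -> ICCResult:
    """Class-1 ICC per column from two (subjects x variables) measurement arrays.

    The kernel behind :func:`edgewise_icc`; it accepts arbitrary paired
    measurements, not just correlations.
    """
    v1 = np.atleast_2d(np.asarray(first, dtype=float))
    v2 = np.atleast_2d(np.asarray(second, dtype=float))
    if v1.shape != v2.shape:
        raise ValueError("first and second measurement arrays must have equal shape")
    if v1.shape[0] < 2:
        raise ValueError("need at least 2 subjects for ICC")
    mu = (v1 + v2) / 2.0
    sigma = (v1 - v2) ** 2 / 2.0  # sample variance of a pair (divisor 1)
    msr = 2.0 * mu.var(axis=0, ddof=1)
    msw = sigma.mean(axis=0)
    denom = msr + msw
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edge(s) with MSR+MSW=0; ICC set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    icc = np.zeros_like(denom)
    np.divide(msr - msw, denom, out=icc, where=~degenerate)
    np.clip(icc, -1.0, 1.0, out=icc)
    return ICCResult(
        condition=condition,
        icc=icc, msr=msr, msw=msw, mu=mu, sigma=sigma, degenerate=degenerate,
    )


def edgewise_icc(pairs: Sequence[FCPair], idx: EdgeIndex | None = None) -> ICCResult:
    """Class-1 ICC of every FC edge across the two scan halves of one condition."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 subjects for ICC")
    conditions = {p.condition for p in pairs}
    if len(conditions) != 1:
        raise ValueError(f"subjects span multiple conditions: {sorted(conditions)}")
    if idx is None:
        idx = build_edge_index(pairs[0].first.n_regions)
    v1 = np.stack([vectorize_edges(p.first, idx) for p in pairs])
    v2 = np.stack([vectorize_edges(p.second, idx) for p in pairs])
    return icc_from_measurements(v1, v2, condition=pairs[0].condition)


def icc_strength(icc: ICCResult, idx: EdgeIndex) -> ICCStrength:
    """Sum the (non-thresholded) edge ICCs onto each edge's two endpoint regions."""
    if icc.n_edges != idx.n_edges:
        raise ValueError("ICC vector and edge index disagree on edge count")
    strength = np.zeros(idx.n_regions)
    np.add.at(strength, idx.rows, icc.icc)
    np.add.at(strength, idx.cols, icc.icc)
    return ICCStrength(condition=icc.condition, strength=strength)


def threshold_icc_matrix(icc: ICCResult, idx: EdgeIndex, thr: float = 0.6) -> np.ndarray:
    """Binary N x N matrix with 1 where edge ICC strictly exceeds ``thr`` (display aid)."""
    m = np.zeros((idx.n_regions, idx.n_regions), dtype=int)
    hot = icc.icc > thr
    m[idx.rows[hot], idx.cols[hot]] = 1
    m[idx.cols[hot], idx.rows[hot]] = 1
    return m


def zscore_map(values: np.ndarray) -> np.ndarray:
    """Z-score a per-region map across regions (sample SD)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 regions")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; z-scores undefined")
    return (x - x.mean()) / sd


def rsn_icc_contrast(
    icc_a: ICCResult,
    icc_b: ICCResult,
    labels: np.ndarray,
) -> pd.DataFrame:
    """Condition contrast of edge ICC within each of the 28 RSN pairs.

    For every unordered RSN pair: the mean of (icc_a - icc_b) over the member
    edges, a paired t-test pairing edges across conditions, and BH-adjusted p
    over the 28 pairs. Conventionally a = drug, b = placebo, so positive
    differences mean higher idiosyncrasy under the drug.
    """
    if icc_a.n_edges != icc_b.n_edges or icc_a.n_edges != len(labels):
        raise ValueError("ICC vectors and labels must cover the same edges")
    rows = []
    for a, b in rsn_pair_list():
        lab = rsn_pair_label(a, b)
        members = np.flatnonzero(labels == lab)
        if members.size < 2:
            raise ValueError(f"RSN pair {lab} has fewer than 2 edges")
        res = t_test("paired", icc_a.icc[members], icc_b.icc[members])
        rows.append(
            {
                "rsn_a": a,
                "rsn_b": b,
                "label": lab,
                "n_edges": int(members.size),
                "mean_diff": float((icc_a.icc[members] - icc_b.icc[members]).mean()),
                "t": res.statistic,
                "p": res.p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def rsn_strength_contrast(
    str_a: ICCStrength,
    str_b: ICCStrength,
    parc: Parcellation,
) -> pd.DataFrame:
    """Condition contrast of regional ICC strength within each of the 7 RSNs.

    Per RSN: the per-region differences (a - b) across member regions, a
    paired t-test (equivalently one-sample t of the differences against 0),
    and BH-adjusted p over the 7 RSNs.
    """
    if str_a.strength.size != str_b.strength.size or str_a.strength.size != parc.n_regions:
        raise ValueError("strength vectors must match the parcellation")
    rows = []
    for rsn in RSN_LABELS:
        members = parc.regions_in_rsn(rsn)
        if members.size < 2:
            raise ValueError(f"RSN {rsn} has fewer than 2 regions")
        res = t_test("paired", str_a.strength[members], str_b.strength[members])
        rows.append(
            {
                "rsn": rsn,
                "n_regions": int(members.size),
                "mean_diff": float(
                    (str_a.strength[members] - str_b.strength[members]).mean()
                ),
                "t": res.statistic,
                "p": res.p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def rsn_mean_icc_difference_matrix(
    icc_a: ICCResult, icc_b: ICCResult, labels: np.ndarray
) -> np.ndarray:
    """7 x 7 symmetric heatmap of mean ICC difference (a - b) per RSN pair."""
    df = rsn_icc_contrast(icc_a, icc_b, labels)
    m = np.zeros((len(RSN_LABELS), len(RSN_LABELS)))
    order = {name: i for i, name in enumerate(RSN_LABELS)}
    for _, row in df.iterrows():
        i, j = order[row["rsn_a"]], order[row["rsn_b"]]
        m[i, j] = m[j, i] = row["mean_diff"]
    return m
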