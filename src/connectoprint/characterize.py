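"""Interpretation of a predictive edge principal component.

Once a single edge PC (typically PC2, with subject scores y) best predicts
the experience-intensity score b, three views make the pattern legible:

* per-region sums of the PC's loadings over incident selected edges;
* rank-1 "archetype" connectivity: per-subject edge values reconstructed from
  the component and its score, averaged over RSN pairs, then |y|-weighted
  within subjects of positive (rFC y+) and negative (rFC y-) score;
* correlations of b with per-subject mean connectivity of the DMN blocks
  (within-DMN, DMN-limbic, DMN-attentional = DA+VA, DMN-sensory = Vis+SM),
  taken from the real (non-reconstructed) full-scan FCs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_fc import (
    EdgeIndex,
    Parcellation,
    RSN_LABELS,
    rsn_pair_label,
)
from .prediction import EdgePCA, EdgeSelection
from .stats import bh_fdr, pearson_with_p

#: DMN connectivity blocks tested against b. Attentional pools the dorsal and
#: ventral attention networks; sensory pools the visual and somatomotor ones.
DMN_BLOCKS: dict[str, tuple[str, ...]] = {
    "DMN-DMN": (rsn_pair_label("DMN", "DMN"),),
    "DMN-LIM": (rsn_pair_label("DMN", "LIM"),),
    "DMN-attentional": (rsn_pair_label("DMN", "DA"), rsn_pair_label("DMN", "VA")),
    "DMN-sensory": (rsn_pair_label("DMN", "Vis"), rsn_pair_label("DMN", "SM")),
}


@dataclass
class RSNMatrix:
    """7 x 7 symmetric matrix of mean edge values per RSN pair.

    Cells whose RSN pair has no member edge inside the selection are flagged
    undefined (NaN in ``matrix``, False in ``defined``).
    """

    matrix: np.ndarray
    defined: np.ndarray
    provenance: str = ""


def region_coefficient_map(
    pca: EdgePCA,
    component: int,
    sel: EdgeSelection,
    idx: EdgeIndex,
) -> np.ndarray:
    """Sum a component's loadings over each region's incident selected edges.

    ``component`` is 1-based (component 2 = the y pattern). Satisfies the
    handshake identity: the map sums to twice the loading total.
    """
    if not 1 <= component <= pca.k:
        raise ValueError(f"component must lie in [1, {pca.k}]")
    w = pca.loadings[component - 1]
    out = np.zeros(idx.n_regions)
    np.add.at(out, idx.rows[sel.ids], w)
    np.add.at(out, idx.cols[sel.ids], w)
    return out


def reconstruct_rank1(pca: EdgePCA, component: int = 2) -> np.ndarray:
    """Per-subject edge vectors rebuilt from one component and its scores.

    Returns (s x n): column means plus score_i * loading vector. The mean is
    included so the reconstruction reads as connectivity levels rather than
    deviations.
    """
    if not 1 <= component <= pca.k:
        raise ValueError(f"component must lie in [1, {pca.k}]")
    c = component - 1
    return pca.column_means[None, :] + np.outer(pca.scores[:, c], pca.loadings[c])


def rsn_average_fc(
    edge_values: np.ndarray,
    sel: EdgeSelection | np.ndarray,
    labels: np.ndarray,
    provenance: str = "",
) -> RSNMatrix:
    """Mean edge value per RSN pair over a selection.

    ``edge_values`` are the values of the selected edges (length n, in
    selection order); ``labels`` are the per-edge RSN-pair labels of the FULL
    edge index, which the selection indexes into.
    """
    ids = sel.ids if isinstance(sel, EdgeSelection) else np.asarray(sel, dtype=int)
    edge_values = np.asarray(edge_values, dtype=float)
    if edge_values.shape != (ids.size,):
        raise ValueError("edge_values must align with the selection")
    sel_labels = labels[ids]
    m = np.full((len(RSN_LABELS), len(RSN_LABELS)), np.nan)
    defined = np.zeros_like(m, dtype=bool)
    order = {name: i for i, name in enumerate(RSN_LABELS)}
    for i, a in enumerate(RSN_LABELS):
        for b in RSN_LABELS[i:]:
            lab = rsn_pair_label(a, b)
            members = sel_labels == lab
            if members.any():
                j = order[b]
                m[i, j] = m[j, i] = edge_values[members].mean()
                defined[i, j] = defined[j, i] = True
    return RSNMatrix(matrix=m, defined=defined, provenance=provenance)


def archetype_matrices(
    rsn_per_subject: Sequence[RSNMatrix],
    y: np.ndarray,
) -> tuple[RSNMatrix | None, RSNMatrix | None]:
    """|y|-weighted average RSN matrices over positive-y and negative-y subjects.

    rFC y+ = sum_{y_i > 0} |y_i| M_i / sum |y_i| (and analogously for y-).
    Subjects with y exactly 0 contribute to neither archetype. A side with no
    subjects is returned as None.
    """
    y = np.asarray(y, dtype=float)
    if len(rsn_per_subject) != y.size:
        raise ValueError("one RSN matrix per subject required")
    stack = np.stack([r.matrix for r in rsn_per_subject])
    defined = np.stack([r.defined for r in rsn_per_subject]).all(axis=0)

    def side(mask: np.ndarray, tag: str) -> RSNMatrix | None:
        if not mask.any():
            return None
        w = np.abs(y[mask])
        avg = np.einsum("s,sij->ij", w, stack[mask]) / w.sum()
        return RSNMatrix(matrix=avg, defined=defined, provenance=tag)

    return side(y > 0, "reconstructed_y_plus"), side(y < 0, "reconstructed_y_minus")


def dmn_behavior_correlations(
    edge_matrix: np.ndarray,
    sel: EdgeSelection | np.ndarray | None,
    labels: np.ndarray,
    b: np.ndarray,
) -> pd.DataFrame:
    """Correlate b with per-subject mean connectivity of the four DMN blocks.

    ``edge_matrix`` is subjects x all-edges (real full-scan FC values);
    ``sel=None`` computes the all-edge control variant. Returns one row per
    block with the per-subject means, Pearson r, two-sided p, and BH-adjusted
    p over the four blocks.
    """
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    b = np.asarray(b, dtype=float)
    if b.size < 4:
        raise ValueError("need at least 4 subjects")
    if edge_matrix.shape[0] != b.size:
        raise ValueError("edge matrix and b disagree on subject count")
    if sel is None:
        ids = np.arange(edge_matrix.shape[1])
    else:
        ids = sel.ids if isinstance(sel, EdgeSelection) else np.asarray(sel, dtype=int)
    sel_labels = labels[ids]
    rows = []
    for block, pair_labels in DMN_BLOCKS.items():
        members = np.isin(sel_labels, pair_labels)
        if not members.any():
            raise ValueError(f"block {block} has no edges within the selection")
        per_subject = edge_matrix[:, ids[members]].mean(axis=1)
        res = pearson_with_p(per_subject, b)
        rows.append(
            {
                "block": block,
                "n_edges": int(members.sum()),
                "r": res.statistic,
                "p": res.p,
                "mean_connectivity": per_subject,
            }
        )
    df = pd.DataFrame(rows)
    df["p_fdr"] = bh_fdr(df["p"].to_numpy())
    return df
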