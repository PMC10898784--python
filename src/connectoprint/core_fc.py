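"""Parcellated BOLD time series, split-half functional connectomes, and edge bookkeeping.

A functional connectome (FC) is the symmetric matrix of pairwise Pearson
correlations between the BOLD time series of parcellated cortical regions.
Everything downstream (identifiability, edgewise ICC, prediction) operates on
the upper-triangle "edge vector" of these matrices, so this module owns the
single canonical edge order (row-major upper triangle, ``i < j``) and the
mapping from edges to resting-state-network (RSN) pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The seven canonical cortical resting-state networks (Yeo-style scheme):
#: visual, somatomotor, dorsal attention, ventral attention, limbic,
#: frontoparietal control, default mode.
RSN_LABELS: tuple[str, ...] = ("Vis", "SM", "DA", "VA", "LIM", "FPN", "DMN")

HEMISPHERES: tuple[str, str] = ("L", "R")

CONDITIONS: tuple[str, str] = ("psilocybin", "placebo")

_RSN_INDEX = {name: i for i, name in enumerate(RSN_LABELS)}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionInfo:
    """One cortical region: id, label, hemisphere, RSN membership, unit-sphere centroid."""

    region_id: int
    label: str
    hemisphere: str
    rsn: str
    centroid: np.ndarray  # shape (3,), unit norm

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be L or R, got {self.hemisphere!r}")
        if self.rsn not in RSN_LABELS:
            raise ValueError(f"unknown RSN label {self.rsn!r}")
        c = np.asarray(self.centroid, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"region {self.region_id}: centroid must be a finite 3-vector")
        object.__setattr__(self, "centroid", c)


@dataclass
class Parcellation:
    """An ordered set of cortical regions with RSN labels and spherical centroids."""

    regions: list[RegionInfo]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region id(s): {dup}")
        norms = np.linalg.norm(self.centroids, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("centroids must lie on the unit sphere (|norm - 1| <= 1e-9)")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def rsn(self) -> np.ndarray:
        """Per-region RSN label, as an object array of strings."""
        return np.array([r.rsn for r in self.regions], dtype=object)

    @property
    def rsn_index(self) -> np.ndarray:
        """Per-region integer RSN index into :data:`RSN_LABELS`."""
        return np.array([_RSN_INDEX[r.rsn] for r in self.regions], dtype=int)

    @property
    def hemisphere(self) -> np.ndarray:
        return np.array([r.hemisphere for r in self.regions], dtype=object)

    @property
    def centroids(self) -> np.ndarray:
        return np.stack([r.centroid for r in self.regions])

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    def regions_in_rsn(self, rsn: str) -> np.ndarray:
        """Zero-based indices of regions belonging to ``rsn``."""
        if rsn not in RSN_LABELS:
            raise ValueError(f"unknown RSN label {rsn!r}")
        return np.flatnonzero(self.rsn == rsn)


@dataclass
class ParcelTimeSeries:
    """Regional BOLD time series of one subject under one condition.

    ``data`` is regions x timepoints; ``motion`` is the scalar head-motion
    covariate (count of motion-artifact volumes) used in covariate-adjusted
    group comparisons.
    """

    subject_id: str
    condition: str
    data: np.ndarray
    motion: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (regions x timepoints)")
        if self.data.shape[1] < 4:
            raise ValueError("need at least 4 timepoints")
        if np.isnan(self.data).any():
            raise ValueError("time series contains NaN values")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.motion < 0:
            raise ValueError("motion covariate must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical enumeration of the N(N-1)/2 undirected edges of an N-node FC.

    Edges are ordered row-major over the upper triangle: (0,1), (0,2), ...,
    (0,N-1), (1,2), ... so that edge ranks, selections, and PCA loadings are
    comparable across runs.
    """

    n_regions: int
    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)

    @property
    def n_edges(self) -> int:
        return self.rows.size

    @property
    def pairs(self) -> np.ndarray:
        """(n_edges, 2) array of (i, j) with i < j."""
        return np.column_stack([self.rows, self.cols])

    def edge_id_matrix(self) -> np.ndarray:
        """N x N lookup of edge ids (symmetric, -1 on the diagonal)."""
        m = np.full((self.n_regions, self.n_regions), -1, dtype=np.int64)
        ids = np.arange(self.n_edges)
        m[self.rows, self.cols] = ids
        m[self.cols, self.rows] = ids
        return m


@dataclass
class FunctionalConnectome:
    """Symmetric unit-diagonal matrix of pairwise Pearson correlations."""

    matrix: np.ndarray
    half_tag: str  # one of {"first", "second", "full"}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        if np.any(np.abs(m) > 1.0 + 1e-12):
            raise ValueError("FC entries must lie in [-1, 1]")
        if self.half_tag not in ("first", "second", "full"):
            raise ValueError(f"bad half_tag {self.half_tag!r}")
        self.matrix = m

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FCPair:
    """The first-half, second-half, and full-scan FCs of one subject."""

    subject_id: str
    condition: str
    first: FunctionalConnectome
    second: FunctionalConnectome
    full: FunctionalConnectome
    motion: float = 0.0

    def __post_init__(self) -> None:
        n = {self.first.n_regions, self.second.n_regions, self.full.n_regions}
        if len(n) != 1:
            raise ValueError("first/second/full FCs must share one parcellation")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_parcellation(path: str | Path) -> Parcellation:
    """Read a parcellation metadata table.

    Expects a tab-delimited file with header columns
    ``id  label  hemisphere  rsn  x  y  z``. Centroids within 1e-6 of unit
    norm are renormalized exactly; anything further off is an error.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["id", "label", "hemisphere", "rsn", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"parcellation table missing column(s): {missing}")
    if df["id"].duplicated().any():
        dup = sorted(df.loc[df["id"].duplicated(), "id"].unique().tolist())
        raise ValueError(f"duplicate region id(s): {dup}")
    bad_rsn = sorted(set(df["rsn"]) - set(RSN_LABELS))
    if bad_rsn:
        raise ValueError(f"unknown RSN label(s): {bad_rsn}")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite centroid coordinates")
    norms = np.linalg.norm(coords, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        off = int(np.argmax(np.abs(norms - 1.0)))
        raise ValueError(
            f"centroid of region id {df['id'].iloc[off]} is not on the unit sphere "
            f"(norm {norms[off]:.6f})"
        )
    coords = coords / norms[:, None]
    regions = [
        RegionInfo(
            region_id=int(row["id"]),
            label=str(row["label"]),
            hemisphere=str(row["hemisphere"]),
            rsn=str(row["rsn"]),
            centroid=coords[k],
        )
        for k, (_, row) in enumerate(df.iterrows())
    ]
    return Parcellation(regions)


def load_timeseries(
    path: str | Path,
    parc: Parcellation,
    *,
    subject_id: str | None = None,
    condition: str = "placebo",
    motion: float = 0.0,
) -> ParcelTimeSeries:
    """Read a regions x timepoints tab-delimited matrix for one subject.

    Rows must follow the parcellation order. A NaN anywhere is a hard error
    naming the offending region (subjects with corrupted series are excluded
    upstream, never imputed).
    """
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if data.shape[0] != parc.n_regions:
        raise ValueError(
            f"{path.name}: {data.shape[0]} rows but parcellation has "
            f"{parc.n_regions} regions"
        )
    nan_rows = np.flatnonzero(np.isnan(data).any(axis=1))
    if nan_rows.size:
        r = parc.regions[int(nan_rows[0])]
        raise ValueError(f"{path.name}: NaN values in region {r.region_id} ({r.label})")
    return ParcelTimeSeries(
        subject_id=subject_id if subject_id is not None else path.stem,
        condition=condition,
        data=data,
        motion=float(motion),
    )


def load_cohort(manifest_path: str | Path, parc: Parcellation) -> list[ParcelTimeSeries]:
    """Load every subject listed in a cohort manifest CSV.

    The manifest has columns ``subject_id,condition,motion,timeseries_path``;
    relative paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = ["subject_id", "condition", "motion", "timeseries_path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing column(s): {missing}")
    out = []
    for _, row in df.iterrows():
        ts_path = Path(row["timeseries_path"])
        if not ts_path.is_absolute():
            ts_path = manifest_path.parent / ts_path
        out.append(
            load_timeseries(
                ts_path,
                parc,
                subject_id=str(row["subject_id"]),
                condition=str(row["condition"]),
                motion=float(row["motion"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# FC construction
# ---------------------------------------------------------------------------

def split_halves(ts: ParcelTimeSeries) -> tuple[ParcelTimeSeries, ParcelTimeSeries]:
    """Split a scan into two equal-length temporal halves.

    With T timepoints the halves are samples [0, T//2) and [T//2, 2*(T//2));
    for odd T the final sample is dropped so both halves have equal length.
    """
    T = ts.n_timepoints
    if T < 8:
        raise ValueError(f"need at least 8 timepoints to split, got {T}")
    h = T // 2
    first = ParcelTimeSeries(ts.subject_id, ts.condition, ts.data[:, :h], ts.motion)
    second = ParcelTimeSeries(ts.subject_id, ts.condition, ts.data[:, h : 2 * h], ts.motion)
    return first, second


def compute_fc(ts: ParcelTimeSeries, tag: str = "full") -> FunctionalConnectome:
    """Pearson-correlation FC of a regional time-series matrix."""
    sd = ts.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance time series in region index {int(dead[0])} "
            f"(subject {ts.subject_id})"
        )
    m = np.corrcoef(ts.data)
    np.clip(m, -1.0, 1.0, out=m)
    np.fill_diagonal(m, 1.0)
    # enforce exact symmetry against floating-point asymmetries
    m = (m + m.T) / 2.0
    return FunctionalConnectome(matrix=m, half_tag=tag)


def make_fc_pair(ts: ParcelTimeSeries) -> FCPair:
    """First-half, second-half, and full-scan FCs for one subject."""
    first_ts, second_ts = split_halves(ts)
    return FCPair(
        subject_id=ts.subject_id,
        condition=ts.condition,
        first=compute_fc(first_ts, "first"),
        second=compute_fc(second_ts, "second"),
        full=compute_fc(ts, "full"),
        motion=ts.motion,
    )


# ---------------------------------------------------------------------------
# Edge indexing
# ---------------------------------------------------------------------------

def build_edge_index(parc_or_n: Parcellation | int) -> EdgeIndex:
    """Canonical row-major upper-triangle edge enumeration (19,900 edges for N=200)."""
    n = parc_or_n if isinstance(parc_or_n, int) else parc_or_n.n_regions
    if n < 2:
        raise ValueError("need at least 2 regions")
    rows, cols = np.triu_indices(n, k=1)
    return EdgeIndex(n_regions=n, rows=rows, cols=cols)


def vectorize_edges(fc: FunctionalConnectome | np.ndarray, idx: EdgeIndex) -> np.ndarray:
    """Upper-triangle edge vector of an FC, in canonical edge order."""
    m = fc.matrix if isinstance(fc, FunctionalConnectome) else np.asarray(fc, dtype=float)
    if m.shape != (idx.n_regions, idx.n_regions):
        raise ValueError(f"matrix shape {m.shape} does not match edge index N={idx.n_regions}")
    return m[idx.rows, idx.cols].copy()


def edges_to_matrix(vec: np.ndarray, idx: EdgeIndex, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`: rebuild the symmetric matrix."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (idx.n_edges,):
        raise ValueError(f"edge vector length {vec.size} != {idx.n_edges}")
    m = np.full((idx.n_regions, idx.n_regions), float(diagonal))
    m[idx.rows, idx.cols] = vec
    m[idx.cols, idx.rows] = vec
    return m


def rsn_pair_list() -> list[tuple[str, str]]:
    """The 28 unordered RSN pairs (7 within-network + 21 between-network),
    each ordered by the canonical RSN sequence."""
    out = []
    for i, a in enumerate(RSN_LABELS):
        for b in RSN_LABELS[i:]:
            out.append((a, b))
    return out


def rsn_pair_label(a: str, b: str) -> str:
    """Canonical string for an unordered RSN pair, e.g. 'DMN-LIM' -> 'LIM-DMN'."""
    ia, ib = _RSN_INDEX[a], _RSN_INDEX[b]
    if ia <= ib:
        return f"{a}-{b}"
    return f"{b}-{a}"


def edge_rsn_labels(idx: EdgeIndex, parc: Parcellation) -> np.ndarray:
    """Per-edge unordered RSN-pair label (object array of strings like 'Vis-DMN')."""
    if parc.n_regions != idx.n_regions:
        raise ValueError("parcellation and edge index disagree on region count")
    ridx = parc.rsn_index
    table = np.empty((len(RSN_LABELS), len(RSN_LABELS)), dtype=object)
    for i, a in enumerate(RSN_LABELS):
        for j, b in enumerate(RSN_LABELS):
            table[i, j] = rsn_pair_label(a, b)
    return table[ridx[idx.rows], ridx[idx.cols]]


# ---------------------------------------------------------------------------
# Cohort-level convenience
# ---------------------------------------------------------------------------

def fc_pairs_by_condition(cohort: Iterable[ParcelTimeSeries]) -> dict[str, list[FCPair]]:
    """Split-half + full FCs for every subject, grouped by condition."""
    out: dict[str, list[FCPair]] = {}
    for ts in cohort:
        out.setdefault(ts.condition, []).append(make_fc_pair(ts))
    return out


def write_fc_matrices(pairs: Sequence[FCPair], out_dir: str | Path) -> dict:
    """Write per-subject first/second/full FC matrices as TSV; returns a run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {"n_subjects": len(pairs), "files": []}
    for p in pairs:
        for tag, fc in (("first", p.first), ("second", p.second), ("full", p.full)):
            fname = f"{p.subject_id}_{tag}.tsv"
            np.savetxt(out_dir / fname, fc.matrix, delimiter="\t", fmt="%.10g")
            log["files"].append(fname)
    with open(out_dir / "fc_run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return log
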