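"""Idiosyncrasy-informed prediction of subjective drug experience.

Workflow: (1) PCA of the 11-subscale altered-states questionnaire yields the
per-subject intensity score ``b`` (PC1 scores, sign fixed so all-positive
loadings read as "more intense"); (2) an edge subset of size n is chosen —
top-n by edgewise ICC, uniformly at random, or via a spatially contiguous
spin surrogate — and a PCA of the subjects-by-edges matrix of full-scan FC
values yields predictor scores x, y, z (PC1..k, k = 3 by default);
(3) ordinary least squares fits of ``b ~ x + y + z`` (and the single-predictor
variants) are swept over a grid of n, and the ICC-ranked model's R^2 is
compared against an ensemble of 100 random (or spin) models by a two-sided
one-sample t-test, BH-corrected across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_fc import EdgeIndex, Parcellation
from .idiosyncrasy import ICCResult
from .stats import bh_fdr

#: Fixed column order of the 11 altered-states-of-consciousness subdimensions:
#: experience of unity, spiritual experience, blissful state, insightfulness,
#: disembodiment, impaired control and cognition, anxiety, complex imagery,
#: elementary imagery, audiovisual synesthesia, changed meaning of percepts.
ASC_SUBSCALES: tuple[str, ...] = (
    "UN", "SP", "BS", "IS", "DB", "IC", "AX", "CI", "EI", "SY", "CM",
)


# ---------------------------------------------------------------------------
# Behavioral PCA
# ---------------------------------------------------------------------------

@dataclass
class BehavioralPCA:
    coefficients: np.ndarray         # (n_components, 11) orthonormal rows
    scores: np.ndarray               # (s, n_components); column 0 is b
    variance_explained: np.ndarray   # fractions summing to 1
    subject_ids: list[str]

    @property
    def b(self) -> np.ndarray:
        """PC1 subject scores: the overall intensity of the drug experience."""
        return self.scores[:, 0]


def load_behavior(path) -> pd.DataFrame:
    """Read the behavioral table CSV (``subject_id`` + the 11 subscales, fixed order)."""
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", *ASC_SUBSCALES) if c not in df.columns]
    if missing:
        raise ValueError(f"behavior table missing column(s): {missing}")
    if df[list(ASC_SUBSCALES)].isna().any().any():
        raise ValueError("behavior table contains missing values")
    return df[["subject_id", *ASC_SUBSCALES]]


def behavioral_pca(table: pd.DataFrame | np.ndarray) -> BehavioralPCA:
    """PCA of the z-scored 11-subscale behavior table.

    Columns are z-scored (subscales live on heterogeneous sub-score scales),
    then decomposed by SVD. The first component's sign is fixed so its
    coefficient sum is positive, making high b read as an intense experience.
    """
    if isinstance(table, pd.DataFrame):
        subject_ids = (
            table["subject_id"].astype(str).tolist()
            if "subject_id" in table.columns
            else [str(i) for i in range(len(table))]
        )
        X = table[list(ASC_SUBSCALES)].to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        subject_ids = [str(i) for i in range(X.shape[0])]
    s, d = X.shape
    if s < 3:
        raise ValueError("need at least 3 subjects for the behavioral PCA")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"constant behavioral column {ASC_SUBSCALES[dead] if d == 11 else dead}")
    Z = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    if Vt[0].sum() < 0:
        Vt[0] = -Vt[0]
        U[:, 0] = -U[:, 0]
    scores = U * S
    var = S**2
    return BehavioralPCA(
        coefficients=Vt,
        scores=scores,
        variance_explained=var / var.sum(),
        subject_ids=subject_ids,
    )


# ---------------------------------------------------------------------------
# Edge selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeSelection:
    ids: np.ndarray         # unique edge ids, ascending
    method: str             # icc_ranked | random | spin
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=int)
        if ids.size != self.n or np.unique(ids).size != ids.size:
            raise ValueError("selection ids must be unique and of size n")
        object.__setattr__(self, "ids", np.sort(ids))


def select_edges(
    method: str,
    n: int,
    idx: EdgeIndex,
    icc: ICCResult | None = None,
    rng: np.random.Generator | int | None = None,
) -> EdgeSelection:
    """Choose n edges by descending ICC rank or uniformly at random.

    ICC ties are broken by ascending edge id so the top-n set is deterministic.
    """
    if not 3 <= n <= idx.n_edges:
        raise ValueError(f"n must lie in [3, {idx.n_edges}], got {n}")
    if method == "icc_ranked":
        if icc is None:
            raise ValueError("icc_ranked selection requires an ICCResult")
        ids = icc.ranking()[:n]
        return EdgeSelection(ids=ids, method=method, n=n)
    if method == "random":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        ids = gen.choice(idx.n_edges, size=n, replace=False)
        return EdgeSelection(ids=ids, method=method, n=n)
    raise ValueError(f"unknown selection method {method!r}")


# ---------------------------------------------------------------------------
# Spin surrogate
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random 3-D rotation: QR-orthonormalized Gaussian, det +1."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _greedy_match(original: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """Assign each original position to a distinct rotated region.

    Unmatched positions are processed in decreasing order of their distance to
    the nearest still-available rotated centroid, so poorly fitting positions
    pick first. Returns ``perm`` with perm[slot] = source region (local index).
    """
    m = original.shape[0]
    d = np.linalg.norm(original[:, None, :] - rotated[None, :, :], axis=2)
    perm = np.full(m, -1, dtype=int)
    free_rows = np.ones(m, dtype=bool)
    free_cols = np.ones(m, dtype=bool)
    for _ in range(m):
        sub = d[np.ix_(free_rows, free_cols)]
        rows = np.flatnonzero(free_rows)
        cols = np.flatnonzero(free_cols)
        nearest = sub.min(axis=1)
        pick = int(np.argmax(nearest))
        row = rows[pick]
        col = cols[int(np.argmin(sub[pick]))]
        perm[row] = col
        free_rows[row] = False
        free_cols[col] = False
    return perm


def spin_permutation(
    parc: Parcellation,
    rng: np.random.Generator | int | None = None,
    rotation: np.ndarray | None = None,
) -> np.ndarray:
    """Hemisphere-preserving spatial-contiguity null permutation of regions.

    Draws one random rotation for the left hemisphere and applies its
    x-mirrored image to the right hemisphere, then reassigns regions to the
    rotated centroid positions by greedy nearest-neighbor matching without
    replacement. The result is a bijection ``perm`` such that the surrogate
    reads region ``perm[r]``'s data wherever the real analysis reads region
    ``r``. Passing ``rotation=np.eye(3)`` (a test hook) yields the identity.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rot_l = _random_rotation(gen) if rotation is None else np.asarray(rotation, dtype=float)
    mirror = np.diag([-1.0, 1.0, 1.0])
    rot_r = mirror @ rot_l @ mirror
    hemi = parc.hemisphere
    coords = parc.centroids
    perm = np.arange(parc.n_regions)
    for h, rot in (("L", rot_l), ("R", rot_r)):
        members = np.flatnonzero(hemi == h)
        if members.size < 2:
            raise ValueError(f"hemisphere {h} has fewer than 2 regions")
        x = coords[members]
        local = _greedy_match(x, x @ rot.T)
        perm[members] = members[local]
    return perm


def permuted_edge_columns(
    sel: EdgeSelection | np.ndarray, perm: np.ndarray, idx: EdgeIndex
) -> np.ndarray:
    """Edge ids that a spin surrogate reads for the selected region pairs.

    The surrogate keeps the selected (i, j) pairs but reads the FC values of
    (perm[i], perm[j]); since perm is a bijection the mapped pairs are again
    valid edges.
    """
    ids = sel.ids if isinstance(sel, EdgeSelection) else np.asarray(sel, dtype=int)
    eid = idx.edge_id_matrix()
    pi = perm[idx.rows[ids]]
    pj = perm[idx.cols[ids]]
    return eid[pi, pj]


# ---------------------------------------------------------------------------
# Edge PCA
# ---------------------------------------------------------------------------

@dataclass
class EdgePCA:
    """PCA of a subjects x selected-edges matrix of full-scan FC values.

    Columns are mean-centered but not scaled (all edges already live on the
    correlation scale). Each retained component's sign is fixed so its
    largest-magnitude loading is positive.
    """

    loadings: np.ndarray            # (k, n) orthonormal rows
    scores: np.ndarray              # (s, k); columns are x, y, z, ... for k >= 3
    variance_explained: np.ndarray  # fraction per component, over all components
    column_means: np.ndarray        # (n,) edgewise means removed before the SVD
    k: int

    @property
    def x(self) -> np.ndarray:
        return self.scores[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.scores[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.scores[:, 2]


def edge_pca(edge_matrix: np.ndarray, k: int = 3) -> EdgePCA:
    """PCA of the (subjects x n-selected-edges) FC-value matrix, keeping k components."""
    X = np.asarray(edge_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("edge matrix must be 2-D (subjects x edges)")
    s, n = X.shape
    max_k = min(s - 1, n)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must lie in [1, min(s-1, n)] = [1, {max_k}], got {k}")
    if s < k + 1:
        raise ValueError("need at least k+1 subjects")
    means = X.mean(axis=0)
    Xc = X - means
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for c in range(min(s, n)):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] = -Vt[c]
            U[:, c] = -U[:, c]
    var = S**2
    total = var.sum()
    return EdgePCA(
        loadings=Vt[:k].copy(),
        scores=(U * S)[:, :k].copy(),
        variance_explained=var / total if total > 0 else var,
        column_means=means,
        k=k,
    )


# ---------------------------------------------------------------------------
# Linear models
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    r2: float
    p: float
    df_model: int
    df_resid: int


def fit_linear_model(b: np.ndarray, predictors: np.ndarray,
                     names: Sequence[str] | None = None) -> ModelFit:
    """OLS fit of b on the given predictor scores (with intercept).

    Significance is the overall F-test for multi-predictor models and the
    correlation t-test for a single predictor (identical p; reported on the
    scale practitioners expect for each case).
    """
    b = np.asarray(b, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    s, p_count = X.shape
    if b.shape != (s,):
        raise ValueError("b and predictors disagree on subject count")
    design = np.column_stack([np.ones(s), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear predictors (rank-deficient design)")
    coef, _, _, _ = np.linalg.lstsq(design, b, rcond=None)
    resid = b - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((b - b.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    r2 = 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    df_model = p_count
    df_resid = s - p_count - 1
    if df_resid <= 0 or ss_res <= ss_tot * 1e-14:
        p_val = 0.0 if r2 > 0 else 1.0
    elif p_count == 1:
        r = np.sign(coef[1]) * np.sqrt(r2)
        t = r * np.sqrt(df_resid / max(1.0 - r * r, 1e-300))
        p_val = float(2.0 * sps.t.sf(abs(t), df_resid))
    else:
        f = (r2 / df_model) / ((1.0 - r2) / df_resid)
        p_val = float(sps.f.sf(f, df_model, df_resid))
    if names is None:
        names = tuple(f"pc{i + 1}" for i in range(p_count))
    return ModelFit(
        predictors=tuple(names),
        coefficients=coef,
        r2=r2,
        p=p_val,
        df_model=df_model,
        df_resid=df_resid,
    )


# ---------------------------------------------------------------------------
# Prediction sweep
# ---------------------------------------------------------------------------

@dataclass
class PredictionSweep:
    """Long-format record of every model fitted over the n-grid.

    ``table`` columns: n, model, replicate, r2, p. Models are ``icc`` (the
    k-predictor ICC-ranked fit), ``icc_pc1``/``icc_pc2``/``icc_pc3`` (... up
    to k) single-predictor variants, and one row per ensemble replicate for
    ``random`` and/or ``spin``.
    """

    table: pd.DataFrame
    n_grid: np.ndarray
    k: int
    ensemble_size: int
    ensembles: tuple[str, ...]
    selections: dict[int, EdgeSelection] = field(default_factory=dict, repr=False)

    def icc_r2(self, n: int) -> float:
        t = self.table
        return float(t.loc[(t["n"] == n) & (t["model"] == "icc"), "r2"].iloc[0])

    def ensemble_r2(self, n: int, ensemble: str = "random") -> np.ndarray:
        t = self.table
        return t.loc[(t["n"] == n) & (t["model"] == ensemble), "r2"].to_numpy()


def default_sweep_grid(n_edges: int, step: int = 250) -> np.ndarray:
    """Prediction grid {step, 2*step, ...} plus a final all-edges point."""
    grid = np.arange(step, n_edges, step)
    return np.append(grid, n_edges)


def prediction_sweep(
    edge_matrix: np.ndarray,
    icc: ICCResult,
    b: np.ndarray,
    idx: EdgeIndex,
    n_grid: np.ndarray | Sequence[int],
    k: int = 3,
    ensembles: Sequence[str] = ("random",),
    ensemble_size: int = 100,
    seed: int | None = 0,
    parc: Parcellation | None = None,
) -> PredictionSweep:
    """Fit ICC-ranked and ensemble models of b over a grid of edge counts n.

    ``edge_matrix`` is the (subjects x all-edges) matrix of full-scan FC
    values of the condition under study. Per n the function fits the
    k-predictor ICC-ranked model, its single-predictor variants, and
    ``ensemble_size`` models on random (and optionally spin-surrogate) edge
    selections. The whole sweep is a pure function of its inputs and seed.
    """
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    b = np.asarray(b, dtype=float)
    n_grid = np.asarray(n_grid, dtype=int)
    if np.any(n_grid < k + 1) or np.any(n_grid > idx.n_edges):
        raise ValueError(f"grid must lie in [{k + 1}, {idx.n_edges}]")
    unknown = set(ensembles) - {"random", "spin"}
    if unknown:
        raise ValueError(f"unknown ensemble type(s): {sorted(unknown)}")
    if "spin" in ensembles and parc is None:
        raise ValueError("spin ensemble requires the parcellation")

    ss = np.random.SeedSequence(seed)
    rng_random, rng_spin = (np.random.default_rng(c) for c in ss.spawn(2))

    # Spin permutations are shared across grid points (one ensemble of spatial
    # nulls per sweep), mirroring how a fixed set of rotations is applied to
    # every selection size.
    spin_perms: list[np.ndarray] = []
    if "spin" in ensembles:
        spin_perms = [spin_permutation(parc, rng=rng_spin) for _ in range(ensemble_size)]

    single_names = [f"icc_pc{c + 1}" for c in range(k)]
    rows: list[dict] = []
    selections: dict[int, EdgeSelection] = {}
    for n in n_grid:
        sel = select_edges("icc_ranked", int(n), idx, icc=icc)
        selections[int(n)] = sel
        pca = edge_pca(edge_matrix[:, sel.ids], k=k)
        fit = fit_linear_model(b, pca.scores, names=("x", "y", "z")[:k])
        rows.append({"n": int(n), "model": "icc", "replicate": 0, "r2": fit.r2, "p": fit.p})
        for c in range(k):
            sf = fit_linear_model(b, pca.scores[:, c])
            rows.append(
                {"n": int(n), "model": single_names[c], "replicate": 0,
                 "r2": sf.r2, "p": sf.p}
            )
        if "random" in ensembles:
            for rep in range(ensemble_size):
                rsel = select_edges("random", int(n), idx, rng=rng_random)
                rpca = edge_pca(edge_matrix[:, rsel.ids], k=k)
                rfit = fit_linear_model(b, rpca.scores)
                rows.append(
                    {"n": int(n), "model": "random", "replicate": rep,
                     "r2": rfit.r2, "p": rfit.p}
                )
        if "spin" in ensembles:
            for rep, perm in enumerate(spin_perms):
                cols = permuted_edge_columns(sel, perm, idx)
                spca = edge_pca(edge_matrix[:, cols], k=k)
                sfit = fit_linear_model(b, spca.scores)
                rows.append(
                    {"n": int(n), "model": "spin", "replicate": rep,
                     "r2": sfit.r2, "p": sfit.p}
                )
    return PredictionSweep(
        table=pd.DataFrame(rows),
        n_grid=n_grid,
        k=k,
        ensemble_size=ensemble_size,
        ensembles=tuple(ensembles),
        selections=selections,
    )


def ensemble_comparison(sweep: PredictionSweep, ensemble: str = "random") -> pd.DataFrame:
    """Per-n two-sided one-sample t-test of ensemble R^2 against the ICC-ranked R^2.

    The ICC-ranked model's R^2 serves as the reference mean; p-values are
    BH-corrected across the grid steps. A degenerate zero-variance ensemble is
    reported as p = 1 when it coincides with the reference and p = 0 otherwise.
    """
    if ensemble not in sweep.ensembles:
        raise ValueError(f"sweep has no {ensemble!r} ensemble")
    rows = []
    for n in sweep.n_grid:
        ref = sweep.icc_r2(int(n))
        ens = sweep.ensemble_r2(int(n), ensemble)
        if ens.size < 2:
            raise ValueError("ensemble size must be >= 2 for a t-test")
        if ens.std(ddof=1) == 0:
            t = 0.0 if ens[0] == ref else np.inf * np.sign(ens[0] - ref)
            p = 1.0 if ens[0] == ref else 0.0
        else:
            t, p = sps.ttest_1samp(ens, popmean=ref)
        rows.append(
            {"n": int(n), "ensemble": ensemble, "mean_ensemble_r2": float(ens.mean()),
             "icc_r2": ref, "t": float(t), "p": float(p)}
        )
    df = pd.DataFrame(rows)
    df["p_fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def best_single_predictor(sweep: PredictionSweep) -> dict:
    """The single-predictor ICC-ranked model (component, n) with the smallest p."""
    t = sweep.table
    singles = t[t["model"].str.startswith("icc_pc")]
    best = singles.loc[singles["p"].idxmin()]
    return {
        "model": str(best["model"]),
        "component": int(str(best["model"]).removeprefix("icc_pc")),
        "n": int(best["n"]),
        "r2": float(best["r2"]),
        "p": float(best["p"]),
    }
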