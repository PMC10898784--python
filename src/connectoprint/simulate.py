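"""Synthetic two-condition cohorts with planted fingerprint structure.

The generator emulates the statistical skeleton that the fingerprinting
analysis assumes of a pharmacological resting-state study:

* two conditions (drug, placebo) with 21 and 25 subjects;
* 200 cortical regions in 7 RSNs, split across hemispheres, with unit-sphere
  centroids on a deterministic Fibonacci lattice;
* per subject a stationary zero-mean Gaussian process whose correlation
  matrix is ``C_base + alpha_c * W_i + gamma * G_i + beta * b_i * P``: a
  shared RSN block structure; a subject-fixed idiosyncratic component W_i on
  edges incident to the condition's signature RSNs (frontoparietal under
  placebo; default-mode and visual under the drug), attenuated on edges with
  only one signature endpoint; a diffuse subject-unique component G_i on all
  edges (the nonspecific inter-subject FC heterogeneity of real cohorts,
  which buries weak patterns unless informative edges are selected); and a
  latent-intensity-coupled pattern P concentrated on a fixed DMN core,
  negative on core-DMN and DMN-limbic edges and positive on DMN-attentional
  edges;
* an 11-subscale behavior table whose dominant component is all-positive and
  linearly coupled to the latent intensity b_i (drug subjects only);
* a condition-shifted head-motion covariate that has no effect on the signal
  (it exists to exercise covariate-adjusted group tests).

Both scan halves of a subject are draws from the same correlation matrix, so
split-half FCs are consistent estimates of a subject-stable fingerprint.
Temporal autocorrelation and hemodynamics are deliberately not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_fc import (
    EdgeIndex,
    Parcellation,
    ParcelTimeSeries,
    RegionInfo,
    RSN_LABELS,
    build_edge_index,
    vectorize_edges,
)
from .prediction import ASC_SUBSCALES

#: Region counts per RSN (sum 200), loosely shaped after the relative sizes
#: of the canonical 7-network cortical partition at 200 parcels.
DEFAULT_RSN_SIZES: dict[str, int] = {
    "Vis": 30, "SM": 34, "DA": 26, "VA": 24, "LIM": 14, "FPN": 28, "DMN": 44,
}

#: Subscale gains lambda (arbitrary instrument units). The largest gains sit on
#: insightfulness, experience of unity, blissful state, and changed meaning of
#: percepts, so those subscales dominate the intensity component.
DEFAULT_LAMBDAS: dict[str, float] = {
    "UN": 14.0, "SP": 8.0, "BS": 13.0, "IS": 15.0, "DB": 9.0, "IC": 8.0,
    "AX": 4.0, "CI": 10.0, "EI": 11.0, "SY": 7.0, "CM": 12.0,
}


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic cohort."""

    seed: int = 0
    n_drug: int = 21
    n_placebo: int = 25
    rsn_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_RSN_SIZES))
    timepoints: int = 256
    rho_within: float = 0.35     # baseline correlation inside an RSN
    rho_between: float = 0.05    # baseline correlation between RSNs
    signature_rsns: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"psilocybin": ("DMN", "Vis"), "placebo": ("FPN",)}
    )
    signature_strength: dict[str, float] = field(
        default_factory=lambda: {"psilocybin": 0.075, "placebo": 0.055}
    )
    signature_cross_attenuation: float = 0.6  # W weight on one-signature-endpoint edges
    heterogeneity: float = 0.07       # gamma: per-edge SD of the diffuse subject component
    behavior_coupling: float = 3.4    # beta: gain of the b-coupled pattern P
    pattern_core_per_hemi: int = 12   # DMN core regions per hemisphere carrying P
    pattern_cross_weight: float = 0.2 # |P| on core-LIM/DA/VA edges relative to core-core
    behavior_noise_sd: float = 5.0    # subscale measurement noise (instrument units)
    lambdas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LAMBDAS))
    motion_mean: dict[str, float] = field(
        default_factory=lambda: {"psilocybin": 14.2, "placebo": 10.0}
    )
    motion_sd: float = 7.0
    eig_floor: float = 1e-4           # epsilon: eigenvalue floor of the PD repair
    planted_n: int = 1000             # edge-subset size at which recovery is evaluated

    def __post_init__(self) -> None:
        if set(self.rsn_sizes) != set(RSN_LABELS):
            raise ValueError("rsn_sizes must cover exactly the 7 RSNs")
        if any(v < 2 for v in self.rsn_sizes.values()):
            raise ValueError("every RSN needs at least 2 regions")
        for d in (self.signature_strength, self.motion_mean):
            if set(d) != {"psilocybin", "placebo"}:
                raise ValueError("per-condition parameters must cover both conditions")
        if any(v < 0 for v in self.signature_strength.values()):
            raise ValueError("signature strengths must be >= 0")
        if self.behavior_coupling < 0 or self.heterogeneity < 0:
            raise ValueError("strengths must be >= 0")
        if not 0 <= self.signature_cross_attenuation <= 1:
            raise ValueError("signature_cross_attenuation must lie in [0, 1]")
        if self.pattern_cross_weight < 0:
            raise ValueError("pattern_cross_weight must be >= 0")
        n_dmn_hemi = min(
            self.rsn_sizes["DMN"] // 2 + self.rsn_sizes["DMN"] % 2,
            self.rsn_sizes["DMN"] // 2,
        )
        if not 1 <= self.pattern_core_per_hemi <= n_dmn_hemi:
            raise ValueError("pattern_core_per_hemi exceeds DMN regions per hemisphere")
        if set(self.lambdas) != set(ASC_SUBSCALES):
            raise ValueError("lambdas must cover exactly the 11 subscales")
        if any(v <= 0 for v in self.lambdas.values()):
            raise ValueError("lambdas must be positive")
        if self.timepoints < 8:
            raise ValueError("timepoints must be >= 8")

    @property
    def n_regions(self) -> int:
        return sum(self.rsn_sizes.values())


@dataclass
class SyntheticCohort:
    """In-memory cohort plus the ground truth needed for recovery tests."""

    config: SimConfig
    parcellation: Parcellation
    timeseries: list[ParcelTimeSeries]
    behavior: pd.DataFrame                 # drug subjects only
    b_true: dict[str, float]               # latent intensity per drug subject
    pattern_edge_ids: np.ndarray           # edges where P is nonzero
    pattern_weights: np.ndarray            # signed P weights on those edges
    covariances: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def truth_payload(self) -> dict:
        return {
            "b_true": self.b_true,
            "pattern_edge_ids": self.pattern_edge_ids.tolist(),
            "pattern_weights": self.pattern_weights.tolist(),
            "signature_rsns": {
                k: list(v) for k, v in self.config.signature_rsns.items()
            },
            "planted_n": self.config.planted_n,
        }


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

def _fibonacci_sphere(m: int) -> np.ndarray:
    """Deterministic quasi-uniform lattice of m points on the unit sphere."""
    i = np.arange(m, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / m
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_parcellation(config: SimConfig) -> Parcellation:
    """Deterministic synthetic parcellation: per-RSN regions split L/R.

    Within each hemisphere regions follow the canonical RSN order; an RSN with
    an odd region count places the extra region in the left hemisphere. Left
    centroids come from a Fibonacci lattice; right centroids are the
    x-mirrored lattice, giving a bilaterally symmetric layout.
    """
    counts = {
        h: {
            rsn: (config.rsn_sizes[rsn] + (1 if h == "L" else 0)) // 2
            for rsn in RSN_LABELS
        }
        for h in ("L", "R")
    }
    lattices = {}
    for h in ("L", "R"):
        m = sum(counts[h].values())
        pts = _fibonacci_sphere(m)
        if h == "R":
            pts = pts * np.array([-1.0, 1.0, 1.0])
        lattices[h] = pts
    regions: list[RegionInfo] = []
    rid = 1
    for h in ("L", "R"):
        cursor = 0
        for rsn in RSN_LABELS:
            for k in range(counts[h][rsn]):
                regions.append(
                    RegionInfo(
                        region_id=rid,
                        label=f"{h}_{rsn}_{k + 1}",
                        hemisphere=h,
                        rsn=rsn,
                        centroid=lattices[h][cursor],
                    )
                )
                rid += 1
                cursor += 1
    return Parcellation(regions)


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------

def base_covariance(parc: Parcellation, rho_within: float, rho_between: float) -> np.ndarray:
    """Shared RSN block structure: rho_within inside an RSN, rho_between elsewhere."""
    ridx = parc.rsn_index
    same = ridx[:, None] == ridx[None, :]
    c = np.where(same, rho_within, rho_between).astype(float)
    np.fill_diagonal(c, 1.0)
    return c


def dmn_core_mask(parc: Parcellation, core_per_hemi: int) -> np.ndarray:
    """Fixed DMN 'core': the first core_per_hemi DMN regions of each hemisphere.

    Emulates the empirical concentration of the predictive pattern on a
    posterior-medial/prefrontal subset of the default-mode network rather
    than the network as a whole.
    """
    dmn = parc.rsn == "DMN"
    hemi = parc.hemisphere
    core = np.zeros(parc.n_regions, dtype=bool)
    for h in ("L", "R"):
        members = np.flatnonzero(dmn & (hemi == h))
        core[members[:core_per_hemi]] = True
    return core


def planted_pattern(parc: Parcellation, config: SimConfig | None = None) -> np.ndarray:
    """Unit-Frobenius b-coupled pattern P as an N x N matrix.

    Weight -1 on edges within the DMN core, -cross_weight on core-to-limbic
    edges, +cross_weight on core-to-attentional (DA, VA) edges, zero
    elsewhere; normalized to unit Frobenius norm so the coupling gain beta is
    comparable across configurations. The sign structure mirrors the
    directionality of the drug-intensity FC pattern the analysis is meant to
    recover: intense experiences go with reduced within-DMN and DMN-limbic
    and raised DMN-attentional connectivity.
    """
    if config is None:
        config = SimConfig()
    rsn = parc.rsn
    n = parc.n_regions
    core = dmn_core_mask(parc, config.pattern_core_per_hemi)
    cw = config.pattern_cross_weight
    p = np.zeros((n, n))
    p[np.outer(core, core)] = -1.0
    for other, wgt in (("LIM", -cw), ("DA", cw), ("VA", cw)):
        mask_other = rsn == other
        block = np.outer(core, mask_other) | np.outer(mask_other, core)
        p[block] = wgt
    np.fill_diagonal(p, 0.0)
    return p / np.linalg.norm(p)


def _signature_weight(
    parc: Parcellation, rsns: tuple[str, ...], attenuation: float
) -> np.ndarray:
    """Per-edge weight of the signature component W.

    1 on edges with both endpoints inside the signature RSNs, ``attenuation``
    on edges with exactly one signature endpoint, 0 elsewhere.
    """
    member = np.isin(parc.rsn.astype(str), list(rsns))
    n_sig = member[:, None].astype(int) + member[None, :].astype(int)
    weight = np.where(n_sig == 2, 1.0, np.where(n_sig == 1, attenuation, 0.0))
    np.fill_diagonal(weight, 0.0)
    return weight


def nearest_correlation_repair(sigma: np.ndarray, eig_floor: float) -> np.ndarray:
    """Clip eigenvalues at the floor and rescale to unit diagonal."""
    sym = (sigma + sigma.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.maximum(w, eig_floor)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    return fixed


def make_subject_covariance(
    config: SimConfig,
    parc: Parcellation,
    condition: str,
    b_true: float,
    rng: np.random.Generator,
    base: np.ndarray | None = None,
    pattern: np.ndarray | None = None,
) -> np.ndarray:
    """One subject's target correlation matrix.

    ``Sigma = C_base + alpha_c * W + gamma * G + beta * b_true * P``, with W
    a subject-fixed symmetric standard-Gaussian perturbation on edges
    incident to the condition's signature RSNs (attenuated when only one
    endpoint is a signature region) and G an unlocalized symmetric Gaussian
    perturbation on all edges, followed by eigenvalue clipping at the floor
    and rescaling to unit diagonal.
    """
    if base is None:
        base = base_covariance(parc, config.rho_within, config.rho_between)
    if pattern is None:
        pattern = planted_pattern(parc, config)
    n = parc.n_regions
    weight = _signature_weight(
        parc, config.signature_rsns[condition], config.signature_cross_attenuation
    )
    iu = np.triu_indices(n, k=1)
    w = np.zeros((n, n))
    w[iu] = rng.standard_normal(iu[0].size)
    w = (w + w.T) * weight
    g = np.zeros((n, n))
    g[iu] = rng.standard_normal(iu[0].size)
    g = g + g.T
    sigma = (
        base
        + config.signature_strength[condition] * w
        + config.heterogeneity * g
        + config.behavior_coupling * b_true * pattern
    )
    repaired = nearest_correlation_repair(sigma, config.eig_floor)
    assert np.linalg.eigvalsh(repaired).min() > 0, "PD repair failed"
    return repaired


def sample_timeseries(
    sigma: np.ndarray, timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """T independent draws from N(0, Sigma) as a regions x T matrix."""
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance is not positive definite") from err
    return chol @ rng.standard_normal((sigma.shape[0], timepoints))


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def make_behavior(
    b_true: np.ndarray,
    subject_ids: list[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """11-subscale behavior table coupled to the latent intensity.

    ``subscale_j = lambda_j * (b_i - min(b)) + noise``, clipped at 0 so all
    scores are nonnegative like the instrument's sub-scores. With positive
    gains the dominant principal component has all-positive coefficients.
    """
    b = np.asarray(b_true, dtype=float)
    lam = np.array([config.lambdas[c] for c in ASC_SUBSCALES])
    signal = np.outer(b - b.min(), lam)
    noise = rng.normal(scale=config.behavior_noise_sd, size=signal.shape)
    scores = np.clip(signal + noise, 0.0, None)
    df = pd.DataFrame(scores, columns=list(ASC_SUBSCALES))
    df.insert(0, "subject_id", subject_ids)
    return df


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort (and optionally write it to disk).

    The on-disk tree (parcellation.tsv, manifest.csv, timeseries/<id>.tsv,
    behavior.csv, truth.json) is loadable end-to-end by the pipeline loaders
    and is byte-identical across runs with the same config.
    """
    parc = make_parcellation(config)
    idx = build_edge_index(parc)
    base = base_covariance(parc, config.rho_within, config.rho_between)
    pattern = planted_pattern(parc, config)
    pat_edges = vectorize_edges(pattern, idx)
    nonzero = np.flatnonzero(pat_edges != 0)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    drug_ids = [f"psi{i + 1:02d}" for i in range(config.n_drug)]
    placebo_ids = [f"pla{i + 1:02d}" for i in range(config.n_placebo)]
    b_drug = rng.standard_normal(config.n_drug)

    motion_vals = {}
    for cond, ids in (("psilocybin", drug_ids), ("placebo", placebo_ids)):
        draws = rng.normal(config.motion_mean[cond], config.motion_sd, size=len(ids))
        for sid, m in zip(ids, draws):
            motion_vals[sid] = float(np.round(np.clip(m, 0.0, None)))

    timeseries: list[ParcelTimeSeries] = []
    covariances: dict[str, np.ndarray] = {}
    b_map: dict[str, float] = {}
    for cond, ids, bvals in (
        ("psilocybin", drug_ids, b_drug),
        ("placebo", placebo_ids, np.zeros(config.n_placebo)),
    ):
        for sid, b in zip(ids, bvals):
            sigma = make_subject_covariance(
                config, parc, cond, float(b), rng, base=base, pattern=pattern
            )
            data = sample_timeseries(sigma, config.timepoints, rng)
            timeseries.append(
                ParcelTimeSeries(
                    subject_id=sid, condition=cond, data=data, motion=motion_vals[sid]
                )
            )
            covariances[sid] = sigma
            if cond == "psilocybin":
                b_map[sid] = float(b)

    behavior = make_behavior(b_drug, drug_ids, config, rng)
    cohort = SyntheticCohort(
        config=config,
        parcellation=parc,
        timeseries=timeseries,
        behavior=behavior,
        b_true=b_map,
        pattern_edge_ids=nonzero,
        pattern_weights=pat_edges[nonzero],
        covariances=covariances,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    rows = [
        {
            "id": r.region_id,
            "label": r.label,
            "hemisphere": r.hemisphere,
            "rsn": r.rsn,
            "x": r.centroid[0],
            "y": r.centroid[1],
            "z": r.centroid[2],
        }
        for r in parc.regions
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write the cohort tree with fixed formatting (deterministic bytes)."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    write_parcellation(cohort.parcellation, out / "parcellation.tsv")
    manifest_rows = []
    for ts in cohort.timeseries:
        rel = f"timeseries/{ts.subject_id}.tsv"
        np.savetxt(out / rel, ts.data, delimiter="\t", fmt="%.6f")
        manifest_rows.append(
            {
                "subject_id": ts.subject_id,
                "condition": ts.condition,
                "motion": ts.motion,
                "timeseries_path": rel,
            }
        )
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    cohort.behavior.to_csv(out / "behavior.csv", index=False, float_format="%.6f")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth_payload(), fh, indent=2, sort_keys=True)
    return out


def config_from_mapping(mapping: dict) -> SimConfig:
    """Build a SimConfig from a plain (e.g. YAML-loaded) mapping."""
    cfg = SimConfig()
    known = set(asdict(cfg))
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    merged = {**asdict(cfg), **mapping}
    merged["signature_rsns"] = {
        k: tuple(v) for k, v in merged["signature_rsns"].items()
    }
    return SimConfig(**merged)
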