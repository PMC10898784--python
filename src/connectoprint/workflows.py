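"""End-to-end convenience workflows over the module-level building blocks.

These functions wire the canonical pipeline together — split-half FCs,
fingerprint metrics with covariate-adjusted group tests, edgewise ICC maps,
the idiosyncrasy-informed prediction sweep, and DMN characterization — and
are what the examples, the command-line interface, and the reproduction
script call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .characterize import dmn_behavior_correlations
from .core_fc import (
    EdgeIndex,
    FCPair,
    ParcelTimeSeries,
    Parcellation,
    build_edge_index,
    edge_rsn_labels,
    fc_pairs_by_condition,
    vectorize_edges,
)
from .fingerprint import fingerprint_metrics, identifiability_matrix
from .idiosyncrasy import ICCResult, edgewise_icc, icc_strength, rsn_strength_contrast
from .prediction import (
    EdgePCA,
    behavioral_pca,
    edge_pca,
    ensemble_comparison,
    prediction_sweep,
    select_edges,
)
from .simulate import SyntheticCohort
from .stats import TestResult, group_effect_with_covariate


def condition_edge_matrix(pairs: Sequence[FCPair], idx: EdgeIndex) -> np.ndarray:
    """(subjects x all-edges) matrix of full-scan FC values."""
    return np.stack([vectorize_edges(p.full, idx) for p in pairs])


@dataclass
class FingerprintSummary:
    metrics: pd.DataFrame                       # per-subject Iself/Iothers/Idiff
    group_tests: dict[str, TestResult]          # per metric, drug-vs-placebo adjusted for motion
    group_means: pd.DataFrame


def fingerprint_summary(
    pairs_by_condition: Mapping[str, Sequence[FCPair]],
    idx: EdgeIndex,
) -> FingerprintSummary:
    """Per-condition identifiability metrics plus motion-adjusted group effects.

    Group tests regress each metric on ``group + motion`` (group coded 1 for
    the drug condition), reporting the group coefficient's t and p.
    """
    frames = []
    for cond, pairs in pairs_by_condition.items():
        m = fingerprint_metrics(identifiability_matrix(pairs, idx))
        df = m.to_frame()
        df["motion"] = [p.motion for p in pairs]
        frames.append(df)
    metrics = pd.concat(frames, ignore_index=True)
    group = (metrics["condition"] == "psilocybin").to_numpy(dtype=float)
    motion = metrics["motion"].to_numpy()
    tests = {
        name: group_effect_with_covariate(metrics[name].to_numpy(), group, motion)
        for name in ("iself", "iothers", "idiff")
    }
    means = metrics.groupby("condition")[["iself", "iothers", "idiff"]].mean()
    return FingerprintSummary(metrics=metrics, group_tests=tests, group_means=means)


@dataclass
class CohortAnalysis:
    """Everything the downstream analyses need, computed once from a cohort."""

    parc: Parcellation
    idx: EdgeIndex
    labels: np.ndarray
    pairs_by_condition: dict[str, list[FCPair]]
    icc: dict[str, ICCResult]
    fingerprints: FingerprintSummary
    edge_matrix_drug: np.ndarray
    b: np.ndarray
    behavioral_var_explained: np.ndarray


def analyze_cohort(
    cohort_ts: Sequence[ParcelTimeSeries],
    parc: Parcellation,
    behavior: pd.DataFrame,
) -> CohortAnalysis:
    """Run the deterministic first half of the pipeline on a loaded cohort."""
    idx = build_edge_index(parc)
    labels = edge_rsn_labels(idx, parc)
    pairs = fc_pairs_by_condition(cohort_ts)
    icc = {cond: edgewise_icc(p, idx) for cond, p in pairs.items()}
    fps = fingerprint_summary(pairs, idx)
    drug_pairs = pairs["psilocybin"]
    order = {p.subject_id: k for k, p in enumerate(drug_pairs)}
    behavior = behavior.set_index("subject_id").loc[
        [p.subject_id for p in drug_pairs]
    ].reset_index()
    bpca = behavioral_pca(behavior)
    return CohortAnalysis(
        parc=parc,
        idx=idx,
        labels=labels,
        pairs_by_condition=pairs,
        icc=icc,
        fingerprints=fps,
        edge_matrix_drug=condition_edge_matrix(drug_pairs, idx),
        b=bpca.b,
        behavioral_var_explained=bpca.variance_explained,
    )


def planted_pattern_recovery(
    analysis: CohortAnalysis,
    pattern_edge_ids: np.ndarray,
    pattern_weights: np.ndarray,
    n: int,
    k: int = 3,
) -> dict:
    """Correlate the recovered predictive component with the planted pattern.

    Fits the edge PCA on the top-n ICC-ranked drug edges, picks the component
    whose scores correlate best with b (the model selection step of the
    single-predictor analysis), and correlates its loadings with the planted
    pattern weights over the selected edges.
    """
    sel = select_edges("icc_ranked", n, analysis.idx, icc=analysis.icc["psilocybin"])
    pca: EdgePCA = edge_pca(analysis.edge_matrix_drug[:, sel.ids], k=k)
    corrs = [
        abs(np.corrcoef(pca.scores[:, c], analysis.b)[0, 1]) for c in range(k)
    ]
    best_c = int(np.argmax(corrs))
    planted = np.zeros(analysis.idx.n_edges)
    planted[np.asarray(pattern_edge_ids, dtype=int)] = pattern_weights
    planted_sel = planted[sel.ids]
    if planted_sel.std() == 0:
        r_pattern = 0.0
    else:
        r_pattern = float(np.corrcoef(pca.loadings[best_c], planted_sel)[0, 1])
    return {
        "selection": sel,
        "pca": pca,
        "best_component": best_c + 1,
        "score_b_correlation": float(corrs[best_c]),
        "pattern_loading_r": r_pattern,
    }


def recovery_summary(
    cohort: SyntheticCohort,
    ensemble_size: int = 100,
    seed: int = 0,
    k: int = 3,
    ensembles: tuple[str, ...] = ("random",),
) -> dict:
    """One-number-per-question summary of a synthetic cohort's recovery run.

    Used by the replicate-seed recovery checks: fingerprint group effects,
    the DMN/FPN ICC-strength contrast, the ICC-ranked vs random-ensemble
    model comparison at the planted n, pattern-loading recovery, and the
    DMN-block correlations with b.
    """
    analysis = analyze_cohort(cohort.timeseries, cohort.parcellation, cohort.behavior)
    n = cohort.config.planted_n
    sweep = prediction_sweep(
        analysis.edge_matrix_drug,
        analysis.icc["psilocybin"],
        analysis.b,
        analysis.idx,
        n_grid=[n],
        k=k,
        ensembles=ensembles,
        ensemble_size=ensemble_size,
        seed=seed,
        parc=analysis.parc,
    )
    comp = ensemble_comparison(sweep, "random")
    ens_r2 = sweep.ensemble_r2(n, "random")
    spin_mean = (
        float(sweep.ensemble_r2(n, "spin").mean()) if "spin" in ensembles else None
    )
    recovery = planted_pattern_recovery(
        analysis, cohort.pattern_edge_ids, cohort.pattern_weights, n=n, k=k
    )
    strengths = {
        cond: icc_strength(icc, analysis.idx) for cond, icc in analysis.icc.items()
    }
    strength_contrast = rsn_strength_contrast(
        strengths["psilocybin"], strengths["placebo"], analysis.parc
    ).set_index("rsn")
    dmn = dmn_behavior_correlations(
        analysis.edge_matrix_drug, recovery["selection"], analysis.labels, analysis.b
    ).set_index("block")
    means = analysis.fingerprints.group_means
    return {
        "analysis": analysis,
        "iothers_drug_mean": float(means.loc["psilocybin", "iothers"]),
        "iothers_placebo_mean": float(means.loc["placebo", "iothers"]),
        "idiff_drug_mean": float(means.loc["psilocybin", "idiff"]),
        "idiff_placebo_mean": float(means.loc["placebo", "idiff"]),
        "iothers_group_t": analysis.fingerprints.group_tests["iothers"].statistic,
        "idiff_group_t": analysis.fingerprints.group_tests["idiff"].statistic,
        "iself_group_t": analysis.fingerprints.group_tests["iself"].statistic,
        "dmn_strength_t": float(strength_contrast.loc["DMN", "t"]),
        "dmn_strength_mean_diff": float(strength_contrast.loc["DMN", "mean_diff"]),
        "fpn_strength_mean_diff": float(strength_contrast.loc["FPN", "mean_diff"]),
        "icc_r2": sweep.icc_r2(n),
        "ensemble_r2": ens_r2,
        "ensemble_r2_mean": float(ens_r2.mean()),
        "ensemble_r2_q95": float(np.quantile(ens_r2, 0.95)),
        "ensemble_p": float(comp["p"].iloc[0]),
        "spin_r2_mean": spin_mean,
        "pattern_loading_r": recovery["pattern_loading_r"],
        "best_component": recovery["best_component"],
        "dmn_dmn_r": float(dmn.loc["DMN-DMN", "r"]),
        "dmn_dmn_p_fdr": float(dmn.loc["DMN-DMN", "p_fdr"]),
        "dmn_lim_r": float(dmn.loc["DMN-LIM", "r"]),
        "dmn_attentional_r": float(dmn.loc["DMN-attentional", "r"]),
        "dmn_sensory_r": float(dmn.loc["DMN-sensory", "r"]),
        "behavioral_pc1_var_pct": float(
            analysis.behavioral_var_explained[0] * 100.0
        ),
    }
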