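"""Behavioral PCA, edge selection (incl. spin surrogates), edge PCA, and the sweep."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from connectoprint import (
    ASC_SUBSCALES,
    behavioral_pca,
    build_edge_index,
    edge_pca,
    ensemble_comparison,
    fit_linear_model,
    permuted_edge_columns,
    prediction_sweep,
    select_edges,
    spin_permutation,
)
from connectoprint.idiosyncrasy import ICCResult


def _icc_result(values):
    e = len(values)
    return ICCResult(
        condition="psilocybin",
        icc=np.asarray(values, dtype=float),
        msr=np.zeros(e), msw=np.zeros(e),
        mu=np.zeros((2, e)), sigma=np.zeros((2, e)),
        degenerate=np.zeros(e, dtype=bool),
    )


# ---------------------------------------------------------------------------
# behavioral PCA
# ---------------------------------------------------------------------------

def test_behavioral_pca_basics(small_cohort):
    pca = behavioral_pca(small_cohort.behavior)
    assert pca.variance_explained.sum() == pytest.approx(1.0, abs=1e-12)
    # dominant common intensity factor -> all-positive first component
    assert np.all(pca.coefficients[0] > 0)
    # orthonormal coefficient rows
    gram = pca.coefficients @ pca.coefficients.T
    assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)


def test_behavioral_pca_duplication_invariance(small_cohort):
    pca = behavioral_pca(small_cohort.behavior)
    doubled = pd.concat([small_cohort.behavior] * 2, ignore_index=True)
    pca2 = behavioral_pca(doubled)
    assert np.allclose(np.abs(pca2.coefficients[0]), np.abs(pca.coefficients[0]), atol=1e-8)


def test_behavioral_pca_matches_sklearn(small_cohort):
    from sklearn.decomposition import PCA

    X = small_cohort.behavior[list(ASC_SUBSCALES)].to_numpy()
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    ref = PCA().fit(Z)
    ours = behavioral_pca(small_cohort.behavior)
    for c in range(3):
        dot = abs(np.dot(ref.components_[c], ours.coefficients[c]))
        assert dot == pytest.approx(1.0, abs=1e-8)
    assert np.allclose(
        ours.variance_explained[: len(ref.explained_variance_ratio_)],
        ref.explained_variance_ratio_,
        atol=1e-10,
    )


def test_behavioral_pca_rejects_constant_column():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(6, 11))
    X[:, 4] = 2.0
    with pytest.raises(ValueError, match="constant"):
        behavioral_pca(X)


# ---------------------------------------------------------------------------
# edge selection
# ---------------------------------------------------------------------------

def test_select_edges_icc_ranked_with_ties():
    idx = build_edge_index(4)  # 6 edges
    sel = select_edges("icc_ranked", 3, idx, icc=_icc_result([0.9, 0.5, 0.9, 0.1, 0.0, 0.2]))
    assert sorted(sel.ids.tolist()) == [0, 1, 2]
    # tie at the boundary rank: the lower edge id wins
    sel = select_edges("icc_ranked", 3, idx, icc=_icc_result([0.9, 0.8, 0.7, 0.7, 0.0, 0.0]))
    assert sorted(sel.ids.tolist()) == [0, 1, 2]


def test_select_edges_random_is_seeded():
    idx = build_edge_index(30)
    a = select_edges("random", 40, idx, rng=123)
    b = select_edges("random", 40, idx, rng=123)
    c = select_edges("random", 40, idx, rng=124)
    assert np.array_equal(a.ids, b.ids)
    assert not np.array_equal(a.ids, c.ids)
    with pytest.raises(ValueError, match="n must lie"):
        select_edges("random", idx.n_edges + 1, idx, rng=0)


# ---------------------------------------------------------------------------
# spin surrogate
# ---------------------------------------------------------------------------

def test_spin_identity_rotation_gives_identity(small_parc):
    perm = spin_permutation(small_parc, rotation=np.eye(3))
    assert np.array_equal(perm, np.arange(small_parc.n_regions))


def test_spin_is_seeded_hemisphere_preserving_bijection(small_parc):
    hemi = small_parc.hemisphere
    perms = []
    for seed in range(20):
        perm = spin_permutation(small_parc, rng=seed)
        assert sorted(perm.tolist()) == list(range(small_parc.n_regions))
        assert np.all(hemi[perm] == hemi)
        perms.append(perm)
    assert np.array_equal(spin_permutation(small_parc, rng=7), perms[7])
    distinct = {tuple(p) for p in perms}
    assert len(distinct) >= 19  # different seeds give different rotations


def test_permuted_edge_columns_are_valid_edges(small_parc, small_idx):
    sel = select_edges("random", 50, small_idx, rng=1)
    perm = spin_permutation(small_parc, rng=3)
    cols = permuted_edge_columns(sel, perm, small_idx)
    assert cols.shape == (50,)
    assert np.all((cols >= 0) & (cols < small_idx.n_edges))
    ident = permuted_edge_columns(sel, np.arange(small_parc.n_regions), small_idx)
    assert np.array_equal(ident, sel.ids)


# ---------------------------------------------------------------------------
# edge PCA
# ---------------------------------------------------------------------------

def test_edge_pca_reconstruction_and_ordering():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(9, 30))
    k = min(9 - 1, 30)
    pca = edge_pca(X, k=k)
    recon = pca.column_means + pca.scores @ pca.loadings
    assert np.allclose(recon, X, atol=1e-10)
    assert np.all(np.diff(pca.variance_explained) <= 1e-12)
    # sign convention: largest-|loading| entry of each component is positive
    for c in range(k):
        j = np.argmax(np.abs(pca.loadings[c]))
        assert pca.loadings[c, j] > 0


def test_edge_pca_matches_covariance_eigendecomposition():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(12, 20))
    pca = edge_pca(X, k=3)
    Xc = X - X.mean(0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    for c in range(3):
        vec = v[:, order[c]]
        dot = abs(np.dot(vec, pca.loadings[c]))
        assert dot == pytest.approx(1.0, abs=1e-8)
        scores_oracle = Xc @ vec
        r = abs(np.corrcoef(scores_oracle, pca.scores[:, c])[0, 1])
        assert r == pytest.approx(1.0, abs=1e-8)


def test_edge_pca_k_bounds():
    X = np.random.default_rng(0).normal(size=(5, 10))
    with pytest.raises(ValueError, match="k must lie"):
        edge_pca(X, k=5)  # min(s-1, n) = 4


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------

def test_fit_exact_and_null_relationships():
    rng = np.random.default_rng(1)
    y = rng.normal(size=10)
    fit = fit_linear_model(3.0 * y - 1.0, y)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    # response orthogonal to the predictor (constructed) -> R^2 = 0
    x = rng.normal(size=10)
    resid = x - x.mean()
    b = rng.normal(size=10)
    b = b - b.mean()
    b -= (b @ resid) / (resid @ resid) * resid
    fit = fit_linear_model(b, x)
    assert fit.r2 == pytest.approx(0.0, abs=1e-12)


def test_fit_matches_statsmodels_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(9)
    X = rng.normal(size=(15, 3))
    b = rng.normal(size=15)
    fit = fit_linear_model(b, X)
    ref = sm.OLS(b, sm.add_constant(X)).fit()
    assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-10)
    assert fit.p == pytest.approx(ref.f_pvalue, abs=1e-10)
    assert np.allclose(fit.coefficients, ref.params, atol=1e-10)


def test_single_predictor_p_equals_correlation_test():
    rng = np.random.default_rng(4)
    x = rng.normal(size=12)
    b = 0.5 * x + rng.normal(size=12)
    fit = fit_linear_model(b, x)
    r, p = sps.pearsonr(x, b)
    assert fit.r2 == pytest.approx(r**2, abs=1e-12)
    assert fit.p == pytest.approx(p, abs=1e-10)


def test_collinear_predictors_rejected():
    rng = np.random.default_rng(2)
    x = rng.normal(size=10)
    with pytest.raises(ValueError, match="collinear"):
        fit_linear_model(rng.normal(size=10), np.column_stack([x, 2 * x]))


def test_saturated_model_attains_perfect_fit():
    """With k = s - 1 generic predictors every model reaches R^2 = 1."""
    rng = np.random.default_rng(6)
    s = 8
    X = rng.normal(size=(s, s - 1))
    b = rng.normal(size=s)
    assert fit_linear_model(b, X).r2 == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# prediction sweep
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_sweep(small_cohort):
    from connectoprint import analyze_cohort

    analysis = analyze_cohort(
        small_cohort.timeseries, small_cohort.parcellation, small_cohort.behavior
    )
    n = small_cohort.config.planted_n
    sweep = prediction_sweep(
        analysis.edge_matrix_drug,
        analysis.icc["psilocybin"],
        analysis.b,
        analysis.idx,
        n_grid=[n, analysis.idx.n_edges],
        ensembles=("random",),
        ensemble_size=30,
        seed=11,
        parc=analysis.parc,
    )
    return analysis, sweep


def test_full_edge_set_makes_all_models_identical(small_sweep):
    analysis, sweep = small_sweep
    n_all = analysis.idx.n_edges
    icc_r2 = sweep.icc_r2(n_all)
    rand = sweep.ensemble_r2(n_all, "random")
    assert np.allclose(rand, icc_r2, atol=1e-10)


def test_icc_ranked_model_beats_random_mean_on_planted_cohort(small_sweep, small_cohort):
    _, sweep = small_sweep
    n = small_cohort.config.planted_n
    assert sweep.icc_r2(n) > sweep.ensemble_r2(n, "random").mean()


def test_sweep_is_deterministic(small_cohort):
    from connectoprint import analyze_cohort

    analysis = analyze_cohort(
        small_cohort.timeseries, small_cohort.parcellation, small_cohort.behavior
    )
    kwargs = dict(
        n_grid=[50, 120],
        ensembles=("random", "spin"),
        ensemble_size=5,
        seed=3,
        parc=analysis.parc,
    )
    s1 = prediction_sweep(
        analysis.edge_matrix_drug, analysis.icc["psilocybin"], analysis.b,
        analysis.idx, **kwargs,
    )
    s2 = prediction_sweep(
        analysis.edge_matrix_drug, analysis.icc["psilocybin"], analysis.b,
        analysis.idx, **kwargs,
    )
    pd.testing.assert_frame_equal(s1.table, s2.table)


def test_ensemble_comparison_handles_degenerate_and_strong_cases():
    table = pd.DataFrame(
        [{"n": 10, "model": "icc", "replicate": 0, "r2": 0.5, "p": 0.01}]
        + [
            {"n": 10, "model": "random", "replicate": i, "r2": 0.5, "p": 0.5}
            for i in range(5)
        ]
    )
    from connectoprint.prediction import PredictionSweep

    sweep = PredictionSweep(
        table=table, n_grid=np.array([10]), k=3, ensemble_size=5, ensembles=("random",)
    )
    comp = ensemble_comparison(sweep)
    assert comp["p"].iloc[0] == 1.0 and comp["t"].iloc[0] == 0.0

    # ensemble far below the reference with small spread -> significant
    rng = np.random.default_rng(0)
    table2 = pd.DataFrame(
        [{"n": 10, "model": "icc", "replicate": 0, "r2": 0.8, "p": 0.01}]
        + [
            {"n": 10, "model": "random", "replicate": i, "r2": 0.1 + 0.01 * rng.normal(), "p": 0.5}
            for i in range(20)
        ]
    )
    sweep2 = PredictionSweep(
        table=table2, n_grid=np.array([10]), k=3, ensemble_size=20, ensembles=("random",)
    )
    comp2 = ensemble_comparison(sweep2)
    assert comp2["p_fdr"].iloc[0] < 0.05
    assert (comp2["p_fdr"] >= comp2["p"] - 1e-15).all()
    # closed-form check of the one-sample t statistic
    ens = table2.loc[table2["model"] == "random", "r2"].to_numpy()
    t_expected = (ens.mean() - 0.8) / (ens.std(ddof=1) / np.sqrt(len(ens)))
    assert comp2["t"].iloc[0] == pytest.approx(t_expected, abs=1e-10)
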