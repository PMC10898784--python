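"""Edgewise ICC, regional ICC strength, and RSN-level contrasts."""

import numpy as np
import pytest

from connectoprint import (
    ICCResult,
    ICCStrength,
    build_edge_index,
    edge_rsn_labels,
    edgewise_icc,
    icc_from_measurements,
    icc_strength,
    rsn_icc_contrast,
    rsn_strength_contrast,
    threshold_icc_matrix,
    zscore_map,
)


def anova_icc_1_1(data: np.ndarray) -> float:
    """Independent oracle: one-way random-effects ICC(1,1) from ANOVA mean squares.

    data is subjects x k measurements; k = 2 here.
    """
    s, k = data.shape
    grand = data.mean()
    group_means = data.mean(axis=1)
    ss_between = k * ((group_means - grand) ** 2).sum()
    ss_within = ((data - group_means[:, None]) ** 2).sum()
    msb = ss_between / (s - 1)
    msw = ss_within / (s * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


def test_icc_hand_case_one_way_anova():
    """Subjects (1,3) and (5,7): MSR=16, MSW=2, ICC = 7/9."""
    res = icc_from_measurements(np.array([[1.0], [5.0]]), np.array([[3.0], [7.0]]))
    assert res.msr[0] == pytest.approx(16.0)
    assert res.msw[0] == pytest.approx(2.0)
    assert res.icc[0] == pytest.approx(7.0 / 9.0)


def test_icc_degenerate_extremes():
    # identical halves, differing means -> ICC = 1
    first = np.array([[0.1], [0.5], [0.9]])
    res = icc_from_measurements(first, first.copy())
    assert res.icc[0] == pytest.approx(1.0)
    # identical means across subjects, nonzero within variance -> ICC = -1
    res = icc_from_measurements(
        np.array([[0.2], [0.2], [0.2]]), np.array([[0.6], [0.6], [0.6]])
    )
    assert res.icc[0] == pytest.approx(-1.0)
    # all four values equal -> degenerate, ICC defined as 0 with a warning
    with pytest.warns(RuntimeWarning, match="MSR\\+MSW=0"):
        res = icc_from_measurements(np.full((2, 1), 0.3), np.full((2, 1), 0.3))
    assert res.icc[0] == 0.0 and res.degenerate[0]


def test_icc_matches_anova_oracle_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(200):
        s = rng.integers(3, 21)
        first = rng.normal(size=(s, 1))
        second = first + rng.normal(scale=rng.uniform(0.1, 2.0), size=(s, 1))
        res = icc_from_measurements(first, second)
        oracle = anova_icc_1_1(np.hstack([first, second]))
        assert res.icc[0] == pytest.approx(oracle, abs=1e-10)


def test_icc_matches_pingouin_cross_check():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(17)
    for _ in range(5):
        s = int(rng.integers(4, 12))
        first = rng.normal(size=s)
        second = first + rng.normal(scale=0.5, size=s)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(s), 2),
                "raters": np.tile([0, 1], s),
                "scores": np.column_stack([first, second]).ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="scores"
        )
        expected = float(table.loc[table["Type"] == "ICC(1,1)", "ICC"].iloc[0])
        res = icc_from_measurements(first[:, None], second[:, None])
        assert res.icc[0] == pytest.approx(expected, abs=1e-8)


def test_icc_invariances():
    rng = np.random.default_rng(3)
    first = rng.normal(size=(8, 30))
    second = first + rng.normal(scale=0.4, size=(8, 30))
    base = icc_from_measurements(first, second).icc
    # swapping the half labels of any subject leaves ICC unchanged
    f2, s2 = first.copy(), second.copy()
    f2[[1, 4]], s2[[1, 4]] = second[[1, 4]], first[[1, 4]]
    assert np.allclose(icc_from_measurements(f2, s2).icc, base, atol=1e-12)
    # adding a common constant leaves ICC unchanged; positive scaling too
    assert np.allclose(icc_from_measurements(first + 3.7, second + 3.7).icc, base, atol=1e-10)
    assert np.allclose(icc_from_measurements(first * 2.5, second * 2.5).icc, base, atol=1e-10)


def test_edgewise_icc_on_cohort_shapes(small_pairs, small_idx):
    res = edgewise_icc(small_pairs["psilocybin"], small_idx)
    assert res.icc.shape == (small_idx.n_edges,)
    assert np.all((res.icc >= -1) & (res.icc <= 1))
    assert res.mu.shape == (len(small_pairs["psilocybin"]), small_idx.n_edges)


def test_icc_ranking_tie_break_is_ascending_edge_id():
    icc = ICCResult(
        condition="psilocybin",
        icc=np.array([0.9, 0.5, 0.9, 0.1]),
        msr=np.zeros(4), msw=np.zeros(4),
        mu=np.zeros((2, 4)), sigma=np.zeros((2, 4)),
        degenerate=np.zeros(4, dtype=bool),
    )
    assert icc.ranking().tolist() == [0, 2, 1, 3]


# ---------------------------------------------------------------------------
# strength / threshold / z-scores
# ---------------------------------------------------------------------------

def _icc_result(values, condition="psilocybin"):
    e = len(values)
    return ICCResult(
        condition=condition,
        icc=np.asarray(values, dtype=float),
        msr=np.zeros(e), msw=np.zeros(e),
        mu=np.zeros((2, e)), sigma=np.zeros((2, e)),
        degenerate=np.zeros(e, dtype=bool),
    )


def test_icc_strength_constant_and_handshake():
    idx = build_edge_index(6)
    const = _icc_result(np.full(idx.n_edges, 0.4))
    strength = icc_strength(const, idx)
    assert np.allclose(strength.strength, 0.4 * 5)

    rng = np.random.default_rng(8)
    icc = _icc_result(rng.uniform(-1, 1, idx.n_edges))
    strength = icc_strength(icc, idx)
    assert strength.strength.sum() == pytest.approx(2 * icc.icc.sum(), abs=1e-10)
    # brute-force incidence loop
    oracle = np.zeros(6)
    for e, (i, j) in enumerate(idx.pairs):
        oracle[i] += icc.icc[e]
        oracle[j] += icc.icc[e]
    assert np.allclose(strength.strength, oracle, atol=1e-12)


def test_threshold_matrix_strict_and_counts():
    idx = build_edge_index(3)
    m = threshold_icc_matrix(_icc_result([0.61, 0.59, 0.6]), idx, thr=0.6)
    assert m.sum() == 2  # one edge, symmetric
    assert m[0, 1] == 1 and m[1, 0] == 1
    assert np.all(np.diag(m) == 0)
    assert threshold_icc_matrix(_icc_result([0.2, 0.9, 1.0]), idx, thr=1.0).sum() == 0


def test_zscore_map_normalization_and_invariance():
    rng = np.random.default_rng(12)
    x = rng.normal(size=50)
    z = zscore_map(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(zscore_map(3.0 * x + 7.0), z, atol=1e-10)
    assert np.allclose(zscore_map(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])
    with pytest.raises(ValueError, match="zero variance"):
        zscore_map(np.full(5, 2.0))


# ---------------------------------------------------------------------------
# RSN contrasts
# ---------------------------------------------------------------------------

def test_rsn_icc_contrast_trivial_cases(small_parc, small_idx):
    labels = edge_rsn_labels(small_idx, small_parc)
    rng = np.random.default_rng(4)
    icc_a = _icc_result(rng.uniform(0, 1, small_idx.n_edges))
    same = rsn_icc_contrast(icc_a, icc_a, labels)
    assert np.allclose(same["mean_diff"], 0.0)
    assert np.allclose(same["t"], 0.0)
    assert len(same) == 28

    # constant shift on one RSN pair's edges shows up only in that cell
    icc_b = _icc_result(icc_a.icc.copy(), condition="placebo")
    members = labels == "Vis-Vis"
    icc_shift = _icc_result(icc_a.icc + 0.1 * members)
    table = rsn_icc_contrast(icc_shift, icc_b, labels).set_index("label")
    assert table.loc["Vis-Vis", "mean_diff"] == pytest.approx(0.1)
    others = table.drop("Vis-Vis")
    assert np.allclose(others["mean_diff"], 0.0)
    assert (table["p_fdr"] >= table["p"] - 1e-15).all()


def test_rsn_strength_contrast_trivial_cases(small_parc):
    n = small_parc.n_regions
    rng = np.random.default_rng(5)
    base = rng.normal(size=n)
    a = ICCStrength("psilocybin", base.copy())
    b = ICCStrength("placebo", base.copy())
    same = rsn_strength_contrast(a, b, small_parc)
    assert np.allclose(same["t"], 0.0)
    assert len(same) == 7

    shifted = base + 0.5 * (small_parc.rsn == "DMN")
    table = rsn_strength_contrast(
        ICCStrength("psilocybin", shifted), b, small_parc
    ).set_index("rsn")
    assert table.loc["DMN", "mean_diff"] == pytest.approx(0.5)
    assert table.drop("DMN")["mean_diff"].abs().max() == pytest.approx(0.0)
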