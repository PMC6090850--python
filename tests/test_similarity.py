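"""Spearman matrices, UPGMA clustering, floored PCA, fold-change filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neutromap.similarity import (
    cluster_samples,
    fold_change_reproducibility,
    pca_embed,
    select_upregulated_genes,
    spearman_matrix,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Spearman matrix


def brute_spearman(x, y):
    """Oracle: rank both vectors (average ties), then Pearson."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


def test_spearman_duplicate_and_reversed_columns():
    df = pd.DataFrame(
        {"a": [1.0, 2, 3, 4, 5, 6], "b": [1.0, 2, 3, 4, 5, 6], "c": [6.0, 5, 4, 3, 2, 1]}
    )
    corr = spearman_matrix(df)
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)
    np.testing.assert_allclose(np.diag(corr), 1.0)
    np.testing.assert_allclose(corr, corr.T)


def test_spearman_matches_bruteforce(rng):
    df = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
    df.iloc[0, 0] = df.iloc[1, 0]  # inject ties
    corr = spearman_matrix(df)
    for i in "abcd":
        for j in "abcd":
            assert corr.loc[i, j] == pytest.approx(
                brute_spearman(df[i], df[j]), abs=1e-12
            )


def test_spearman_monotone_transform_invariance(rng):
    df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
    transformed = df.copy()
    transformed["b"] = np.exp(3 * transformed["b"]) + 7  # strictly monotone
    np.testing.assert_allclose(spearman_matrix(df), spearman_matrix(transformed), atol=1e-12)


def test_spearman_constant_column_warns():
    df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5], "c": [3.0, 1, 2]})
    with pytest.warns(UserWarning, match="constant"):
        corr = spearman_matrix(df)
    assert np.isnan(corr.loc["a", "b"])
    assert corr.loc["b", "b"] == 1.0


# ---------------------------------------------------------------------------
# UPGMA clustering


def brute_upgma_heights(dist: pd.DataFrame):
    """Oracle: naive UPGMA on a distance matrix, returning merge heights."""
    clusters = {i: [lbl] for i, lbl in enumerate(dist.index)}
    heights = []
    d = {(i, j): dist.iloc[i, j] for i in clusters for j in clusters if i < j}
    next_id = len(clusters)
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters.pop(i) + clusters.pop(j)
        new_d = {}
        for k, members in clusters.items():
            new_d[(min(k, next_id), max(k, next_id))] = np.mean(
                [dist.loc[a, b] for a in merged for b in members]
            )
        clusters[next_id] = merged
        d = {
            (a, b): v
            for (a, b), v in d.items()
            if a not in (i, j) and b not in (i, j)
        }
        d.update(new_d)
        next_id += 1
    return heights


def test_cluster_identical_pair_merges_first():
    corr = pd.DataFrame(
        [[1.0, 1.0, -1.0], [1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]],
        index=list("abc"),
        columns=list("abc"),
    )
    dend = cluster_samples(corr)
    assert dend.heights[0] == pytest.approx(0.0)
    assert (dend.heights >= 0).all() and (dend.heights <= 2).all()


def test_cluster_heights_match_bruteforce(rng):
    n = 5
    x = rng.normal(size=(30, n))
    corr = spearman_matrix(pd.DataFrame(x, columns=list("abcde")))
    dend = cluster_samples(corr)
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    expected = brute_upgma_heights(dist)
    np.testing.assert_allclose(sorted(dend.heights), sorted(expected), atol=1e-12)


def test_cluster_missing_pairs_error():
    corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
    corr.iloc[0, 1] = corr.iloc[1, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        cluster_samples(corr)


def test_cluster_duplicated_sample_merges_at_zero(rng):
    """A duplicated sample joins its twin at height 0 and leaves the first
    real merge unchanged (later UPGMA heights legitimately shift because the
    duplicate leaf carries weight in unweighted averages)."""
    x = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
    base = cluster_samples(spearman_matrix(x))
    x["a2"] = x["a"]
    with_dup = cluster_samples(spearman_matrix(x))
    assert with_dup.heights[0] == pytest.approx(0.0, abs=1e-12)
    assert with_dup.heights[1] == pytest.approx(base.heights[0], abs=1e-12)
    assert (with_dup.heights >= 0).all() and (with_dup.heights <= 2).all()


# ---------------------------------------------------------------------------
# PCA


def test_pca_floors_before_decomposition(rng):
    """PCA at floor f equals PCA of the explicitly pre-floored matrix."""
    m = make_matrix(rng.normal(-2, 1.5, size=(30, 4)), scale="log10")
    emb = pca_embed(m, floor=-2.0)
    pre_floored = make_matrix(m.values.clip(lower=-2.0).to_numpy(), scale="log10")
    ref = pca_embed(pre_floored, floor=-np.inf)
    np.testing.assert_allclose(
        np.abs(emb.coordinates), np.abs(ref.coordinates), atol=1e-9
    )
    assert pre_floored.values.to_numpy().min() == pytest.approx(-2.0)


def test_pca_duplicated_samples_identical_coordinates(rng):
    vals = rng.normal(size=(20, 3))
    vals = np.column_stack([vals, vals[:, 0]])
    m = make_matrix(vals, scale="log10")
    emb = pca_embed(m)
    np.testing.assert_allclose(
        emb.coordinates.loc["s0"], emb.coordinates.loc["s3"], atol=1e-9
    )


def test_pca_variance_fractions_match_eigendecomposition(rng):
    """2-gene toy: fractions equal those of the 2x2 covariance spectrum."""
    vals = rng.normal(size=(2, 6))
    m = make_matrix(vals, scale="log10")
    emb = pca_embed(m, floor=-np.inf)
    cov = np.cov(vals)  # genes are the features
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    np.testing.assert_allclose(emb.variance_ratio, eig / eig.sum(), atol=1e-9)
    assert np.all(np.diff(emb.variance_ratio) <= 1e-12)
    assert emb.variance_ratio.sum() <= 1.0 + 1e-9


def test_pca_translation_invariance(rng):
    vals = rng.normal(size=(15, 4))
    m = make_matrix(vals, scale="log10")
    shifted = make_matrix(vals + 5.0, scale="log10")
    a = pca_embed(m, floor=-np.inf).coordinates.to_numpy()
    b = pca_embed(shifted, floor=-np.inf).coordinates.to_numpy()
    # coordinates agree up to per-component sign
    for k in range(a.shape[1]):
        assert np.allclose(a[:, k], b[:, k], atol=1e-8) or np.allclose(
            a[:, k], -b[:, k], atol=1e-8
        )


def test_pca_too_few_nonconstant_genes():
    m = make_matrix(np.ones((5, 3)), scale="log10")
    with pytest.raises(ValueError, match="non-constant"):
        pca_embed(m)


# ---------------------------------------------------------------------------
# fold-change reproducibility


def _fc_frame(rng, n=50):
    base = rng.normal(0.5, 1.0, n)
    return pd.DataFrame(
        {
            "nutri1": base + rng.normal(0, 0.2, n),
            "dmso1": base,
            "nutri2": base + rng.normal(0, 0.2, n),
            "dmso2": base,
        },
        index=[f"g{i}" for i in range(n)],
    )


def test_fold_change_copied_replicate_is_perfect(rng):
    df = _fc_frame(rng)
    df["nutri2"] = df["nutri1"] - df["dmso1"] + df["dmso2"]  # identical fold changes
    res = fold_change_reproducibility(df, ("nutri1", "dmso1"), ("nutri2", "dmso2"))
    assert res.pearson_r == pytest.approx(1.0)
    assert res.spearman_rho == pytest.approx(1.0)


def test_fold_change_independent_noise_near_zero(rng):
    n = 4000
    df = pd.DataFrame(
        {
            "nutri1": rng.normal(1, 1, n),
            "dmso1": rng.normal(1, 1, n),
            "nutri2": rng.normal(1, 1, n),
            "dmso2": rng.normal(1, 1, n),
        }
    )
    res = fold_change_reproducibility(df, ("nutri1", "dmso1"), ("nutri2", "dmso2"))
    assert abs(res.pearson_r) < 0.06


def test_fold_change_filter_count_matches_hand_count():
    df = pd.DataFrame(
        {
            "nutri1": [2.0, -3.0, 0.0, 1.0, -0.9],
            "dmso1": [1.0, -3.0, 0.5, 1.0, -1.1],
            "nutri2": [2.0, -2.0, 0.0, 1.0, -0.8],
            "dmso2": [1.0, -4.0, 0.5, 1.0, -1.2],
        },
        index=list("abcde"),
    )
    # means: a=1.5, b=-3.0, c=0.25, d=1.0, e=-1.0 -> filter (>= -1) keeps a,c,d,e
    res = fold_change_reproducibility(df, ("nutri1", "dmso1"), ("nutri2", "dmso2"))
    assert set(res.table.index) == {"a", "c", "d", "e"}
    with pytest.raises(ValueError, match="fewer than 3"):
        fold_change_reproducibility(
            df, ("nutri1", "dmso1"), ("nutri2", "dmso2"), min_mean=100.0
        )


# ---------------------------------------------------------------------------
# upregulated gene selection


def test_select_upregulated_boundary_and_conjunction():
    log3 = np.log10(3.0)
    df = pd.DataFrame(
        {
            "nutri1": [1.0 + log3, 1.0 + log3, 1.0],
            "dmso1": [1.0, 1.0, 1.0],
            "nutri2": [1.0 + log3, 1.0, 1.0],
            "dmso2": [1.0, 1.0, 1.0],
        },
        index=["exact3fold", "onlyonepair", "flat"],
    )
    pairs = [("nutri1", "dmso1"), ("nutri2", "dmso2")]
    selected = select_upregulated_genes(df, pairs)
    assert selected == ["exact3fold"]  # inclusive bound; conjunction over pairs


def test_select_upregulated_matches_bruteforce(rng):
    n = 10
    df = pd.DataFrame(
        rng.normal(0, 1, size=(n, 4)),
        columns=["nutri1", "dmso1", "nutri2", "dmso2"],
        index=[f"g{i}" for i in range(n)],
    )
    pairs = [("nutri1", "dmso1"), ("nutri2", "dmso2")]
    selected = set(select_upregulated_genes(df, pairs, min_mean=-1.0, min_fold=3.0))
    expected = set()
    for g in df.index:
        mean_ok = df.loc[g].mean() >= -1.0
        fold_ok = all(
            df.loc[g, t] - df.loc[g, c] >= np.log10(3.0) for t, c in pairs
        )
        if mean_ok and fold_ok:
            expected.add(g)
    assert selected == expected


def test_select_upregulated_unknown_sample_errors():
    df = pd.DataFrame({"a": [1.0], "b": [1.0]})
    with pytest.raises(ValueError, match="not in matrix"):
        select_upregulated_genes(df, [("a", "missing")])
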