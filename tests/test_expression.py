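"""Uniform-gene normalization, log flooring, replicate averaging, restriction."""

import numpy as np
import pandas as pd
import pytest

from neutromap.expression import (
    ExpressionMatrix,
    HomologMap,
    average_replicates,
    compute_scaling_factors,
    filter_gene_type,
    identify_uniform_genes,
    log_transform,
    normalize,
    restrict_to_homologs,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# uniform genes


def brute_force_uniform(values: pd.DataFrame, lower=50, upper=90):
    """Independent oracle: per-sample interval membership, intersected."""
    member = np.ones(len(values), dtype=bool)
    for col in values.columns:
        lo = np.percentile(values[col], lower)
        hi = np.percentile(values[col], upper)
        m = (values[col] >= lo) & (values[col] <= hi)
        if lo == 0:
            m &= values[col] > 0
        member &= m.to_numpy()
    return set(values.index[member])


def test_uniform_genes_single_profile():
    """With one shared profile 1..100, the band is the 50th-90th percentile ranks."""
    vals = np.tile(np.arange(1.0, 101.0)[:, None], (1, 3))
    m = make_matrix(vals)
    uniform = identify_uniform_genes(m)
    expected = brute_force_uniform(m.values)
    assert set(uniform.gene_ids) == expected
    # percentile band of 1..100 with linear interpolation: [50.5, 90.1]
    got = sorted(m.values.iloc[:, 0].loc[list(uniform.gene_ids)])
    assert got[0] >= 50.5 and got[-1] <= 90.1


def test_uniform_genes_matches_bruteforce(rng):
    m = make_matrix(10.0 ** rng.normal(0, 1, size=(30, 3)))
    uniform = identify_uniform_genes(m)
    assert set(uniform.gene_ids) == brute_force_uniform(m.values)


def test_uniform_genes_all_zero_sample_warns():
    vals = np.column_stack([np.arange(1.0, 11.0), np.zeros(10)])
    m = make_matrix(vals)
    with pytest.warns(UserWarning, match="empty"):
        uniform = identify_uniform_genes(m)
    assert len(uniform) == 0


def test_uniform_genes_requires_min_size():
    with pytest.raises(ValueError):
        identify_uniform_genes(make_matrix(np.ones((5, 2))))


# ---------------------------------------------------------------------------
# scaling factors


def all_genes_uniform(matrix):
    """Uniform set spanning every gene (for closed-form factor checks)."""
    from neutromap.expression import UniformGeneSet

    bounds = pd.DataFrame({"lower": 0.0, "upper": np.inf}, index=matrix.samples)
    return UniformGeneSet(tuple(matrix.genes), 0, 100, bounds)


def test_scaling_factor_constant_and_closed_form():
    vals = np.array([[4.0, 1.0], [4.0, 100.0]])
    m = make_matrix(vals)
    factors = compute_scaling_factors(m, all_genes_uniform(m))
    assert factors.factors["s0"] == pytest.approx(4.0)
    assert factors.factors["s1"] == pytest.approx(10.0)  # gmean(1, 100)


def test_scaling_factor_matches_bruteforce(rng):
    m = make_matrix(10.0 ** rng.normal(0, 1, size=(10, 4)))
    uniform = all_genes_uniform(m)
    factors = compute_scaling_factors(m, uniform)
    for s in m.samples:
        expected = np.exp(np.mean(np.log(m.values.loc[list(uniform.gene_ids), s])))
        assert factors.factors[s] == pytest.approx(expected, rel=1e-12)
    assert factors.reference_mean == pytest.approx(factors.factors.mean(), rel=1e-12)


def test_scaling_factor_zero_value_names_offender():
    m = make_matrix([[4.0, 1.0], [0.0, 2.0], [3.0, 3.0]])
    with pytest.raises(ValueError, match="g1"):
        compute_scaling_factors(m, all_genes_uniform(m))


# ---------------------------------------------------------------------------
# normalization


def test_normalize_equal_factors_identity(small_matrix):
    uniform = identify_uniform_genes(small_matrix, lower=0, upper=100)
    factors = compute_scaling_factors(small_matrix, uniform)
    # replace with equal factors: output must equal input
    from neutromap.expression import ScalingFactors

    equal = ScalingFactors(
        pd.Series(2.0, index=small_matrix.samples), 2.0, tuple(small_matrix.samples)
    )
    out = normalize(small_matrix, equal)
    np.testing.assert_allclose(out.values, small_matrix.values)


def test_normalize_scale_invariance(small_matrix):
    """Scaling a non-reference sample pre-normalization is a no-op after.

    The reference mean is anchored on a fixed reference sample, mirroring
    the scheme where a fixed set of human datasets anchors the scale.
    """
    uniform = identify_uniform_genes(small_matrix, lower=0, upper=100)
    base = normalize(
        small_matrix,
        compute_scaling_factors(small_matrix, uniform, reference_samples=["s0"]),
    )
    perturbed_vals = small_matrix.values.copy()
    perturbed_vals["s1"] *= 7.3
    perturbed = small_matrix.with_values(perturbed_vals)
    out = normalize(
        perturbed,
        compute_scaling_factors(perturbed, uniform, reference_samples=["s0"]),
    )
    np.testing.assert_allclose(out.values, base.values, rtol=1e-9)


def test_normalize_equalizes_uniform_geometric_mean(small_matrix):
    uniform = identify_uniform_genes(small_matrix, lower=0, upper=100)
    factors = compute_scaling_factors(small_matrix, uniform)
    out = normalize(small_matrix, factors)
    sub = out.values.loc[list(uniform.gene_ids)]
    gmeans = np.exp(np.log(sub).mean(axis=0))
    np.testing.assert_allclose(gmeans, factors.reference_mean, rtol=1e-9)


def test_normalize_idempotent(small_matrix):
    uniform = identify_uniform_genes(small_matrix, lower=0, upper=100)
    once = normalize(small_matrix, compute_scaling_factors(small_matrix, uniform))
    factors2 = compute_scaling_factors(once, uniform)
    np.testing.assert_allclose(
        factors2.factors, factors2.reference_mean, rtol=1e-9
    )
    twice = normalize(once, factors2)
    np.testing.assert_allclose(twice.values, once.values, rtol=1e-9)


def test_normalize_missing_factor_errors(small_matrix):
    from neutromap.expression import ScalingFactors

    partial = ScalingFactors(pd.Series({"s0": 1.0}), 1.0, ("s0",))
    with pytest.raises(ValueError, match="without scaling factor"):
        normalize(small_matrix, partial)


# ---------------------------------------------------------------------------
# log transform


@pytest.mark.parametrize(
    "value,expected",
    [(0.0, -4.0), (1.0, 0.0), (100.0, 2.0), (1e-6, -4.0), (0.5, np.log10(0.5))],
)
def test_log_transform_values(value, expected):
    """Zeros map to -4; positives to max(log10, floor)."""
    m = make_matrix([[value]])
    out = log_transform(m)
    assert out.values.iloc[0, 0] == pytest.approx(expected)
    assert out.scale == "log10"


def test_log_transform_monotone_and_bounded(rng):
    vals = np.sort(10.0 ** rng.normal(-3, 2, size=50))
    out = log_transform(make_matrix(vals[:, None]))
    col = out.values.iloc[:, 0].to_numpy()
    assert np.all(np.diff(col) >= 0)
    assert col.min() >= -4.0


def test_log_transform_negative_input_errors():
    m = make_matrix([[1.0]])
    m.values.iloc[0, 0] = -1.0  # mutate past construction-time validation
    with pytest.raises(ValueError, match="negative"):
        log_transform(m)


# ---------------------------------------------------------------------------
# replicate averaging


def test_average_replicates_two_stage_hand_example():
    """Lab A replicates (1, 3) average to 2; lab B (8) stays 8; labs average to 5."""
    m = make_matrix(
        [[1.0, 3.0, 8.0]],
        scale="log10",
        lab=["A", "A", "B"],
        condition=["diff"] * 3,
    )
    out = average_replicates(m)
    assert out.values.loc["g0", "diff"] == pytest.approx(5.0)


def test_average_replicates_identity_and_constant():
    single = make_matrix([[2.5]], scale="log10", condition=["x"])
    assert average_replicates(single).values.iloc[0, 0] == pytest.approx(2.5)
    const = make_matrix([[1.5] * 4], scale="log10", lab=list("AABB"), condition=["x"] * 4)
    assert average_replicates(const).values.iloc[0, 0] == pytest.approx(1.5)


def test_average_replicates_permutation_invariant(rng):
    vals = rng.normal(0, 1, size=(5, 4))
    m = make_matrix(vals, lab=list("AABB"), condition=["x"] * 4, scale="log10")
    permuted = make_matrix(
        vals[:, [1, 0, 3, 2]], lab=list("AABB"), condition=["x"] * 4, scale="log10"
    )
    np.testing.assert_allclose(
        average_replicates(m).values, average_replicates(permuted).values
    )


def test_average_replicates_requires_log_scale(small_matrix):
    with pytest.raises(ValueError, match="log10"):
        average_replicates(small_matrix)


# ---------------------------------------------------------------------------
# homolog restriction and gene-type filter


def _two_species_matrices():
    a = make_matrix(np.arange(8, dtype=float).reshape(4, 2) + 1)
    b = make_matrix(np.arange(6, dtype=float).reshape(3, 2) + 1)
    b.values.index = ["h0", "h1", "h2"]
    return a, b


def test_restrict_to_homologs_identity_map():
    a, b = _two_species_matrices()
    hmap = HomologMap([("g0", "h0"), ("g1", "h1"), ("g3", "h2")])
    ra, rb = restrict_to_homologs(a, b, hmap)
    assert list(ra.genes) == ["g0", "g1", "g3"]
    assert list(rb.genes) == ["h0", "h1", "h2"]
    assert ra.n_genes == rb.n_genes


def test_restrict_to_homologs_one_to_many_dropped():
    a, b = _two_species_matrices()
    hmap = HomologMap([("g0", "h0"), ("g0", "h1"), ("g1", "h2")])
    ra, rb = restrict_to_homologs(a, b, hmap)
    # brute force: g0 maps twice -> dropped under one-to-one policy
    assert list(ra.genes) == ["g1"]
    ra2, _ = restrict_to_homologs(a, b, hmap, policy="first_listed")
    assert list(ra2.genes) == ["g0", "g1"]


def test_restrict_to_homologs_empty_overlap_errors():
    a, b = _two_species_matrices()
    with pytest.raises(ValueError, match="overlap"):
        restrict_to_homologs(a, b, HomologMap([("nope", "nah")]))


def test_filter_gene_type_counts():
    m = make_matrix(np.ones((5, 2)))
    ann = {"g0": "protein-coding", "g1": "lncRNA", "g2": "protein-coding",
           "g3": "protein-coding"}  # g4 unannotated
    out = filter_gene_type(m, ann)
    assert list(out.genes) == ["g0", "g2", "g3"]
    with pytest.warns(UserWarning):
        empty = filter_gene_type(m, {}, keep="protein-coding")
    assert empty.n_genes == 0
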