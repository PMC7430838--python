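"""GRM builders against brute-force oracles and the trace contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wblup.grm import (GenotypeDesign, WeightVector, am_weight_vector, build_design,
                       chunk_region_grm, normalize_trace, standardized_grm,
                       vanraden_grm, weighted_grm)
from wblup.io_formats import MISSING, GenotypeTable


def table_from_calls(calls):
    calls = np.asarray(calls, dtype=np.int8)
    m = calls.shape[1]
    snps = pd.DataFrame({"snp": [f"s{j}" for j in range(m)], "chrom": "1",
                         "pos": np.arange(1, m + 1), "allele": "A"})
    return GenotypeTable(samples=[f"i{i}" for i in range(calls.shape[0])],
                        snps=snps, calls=calls)


def random_design(seed, n=20, m=50):
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.1, 0.9, size=m)
    calls = rng.binomial(2, f, size=(n, m))
    # re-draw until no column is monomorphic
    for j in range(m):
        while calls[:, j].min() == calls[:, j].max():
            calls[:, j] = rng.binomial(2, 0.5, size=n)
    return build_design(table_from_calls(calls))


def test_design_formulas_on_single_column():
    d = build_design(table_from_calls([[0], [1], [2]]))
    assert d.freqs[0] == pytest.approx(0.5)
    assert d.X[:, 0] == pytest.approx([-1.0, 0.0, 1.0])
    assert d.W[:, 0] == pytest.approx([-np.sqrt(2), 0.0, np.sqrt(2)])


def test_design_missing_calls_mean_imputed():
    d = build_design(table_from_calls([[0], [2], [MISSING], [2]]))
    # f from observed calls = 4/6; imputed cell sits at 2f, so X column mean is 0
    assert d.freqs[0] == pytest.approx(2 / 3)
    assert d.X[:, 0].mean() == pytest.approx(0.0, abs=1e-12)


def test_design_monomorphic_column_errors():
    with pytest.raises(ValueError, match="s0"):
        build_design(table_from_calls([[2], [2], [2]]))


def test_design_supplied_frequencies_shift_column_means():
    d = build_design(table_from_calls([[0], [1], [2]]), freqs=np.array([0.3]))
    assert abs(d.X[:, 0].mean()) > 0.1  # no error, centering off in-sample


def test_vanraden_two_individuals_one_snp():
    d = build_design(table_from_calls([[0], [2]]))
    G = vanraden_grm(d)
    assert np.allclose(G.values, [[2, -2], [-2, 2]])
    Gw = weighted_grm(d, WeightVector(d=np.ones(1)))
    assert np.allclose(Gw.values, [[2, -2], [-2, 2]])


def brute_force_weighted(d: GenotypeDesign, w):
    n, m = d.n, d.m
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            G[i, k] = sum(w[j] * d.W[i, j] * d.W[k, j] for j in range(m)) / m
    return G


def test_grm_builders_match_naive_loops():
    d = random_design(0)
    denom = np.sum(2 * d.freqs * (1 - d.freqs))
    G_naive = np.zeros((d.n, d.n))
    for i in range(d.n):
        for k in range(d.n):
            G_naive[i, k] = sum(d.X[i, j] * d.X[k, j] for j in range(d.m)) / denom
    assert np.allclose(vanraden_grm(d).values, G_naive, atol=1e-8)

    rng = np.random.default_rng(1)
    w = normalize_trace(rng.uniform(0.1, 3.0, d.m)).d
    assert np.allclose(weighted_grm(d, WeightVector(d=w)).values,
                       brute_force_weighted(d, w), atol=1e-8)
    idx = np.arange(5, 30)
    Wk = d.W[:, idx]
    assert np.allclose(chunk_region_grm(d, idx).values, Wk @ Wk.T / idx.size,
                       atol=1e-12)


def test_duplicate_individuals_duplicate_grm_rows():
    d = build_design(table_from_calls([[0, 1], [0, 1], [2, 1], [1, 0]]))
    G = vanraden_grm(d).values
    assert np.allclose(G[0], G[1])
    assert np.allclose(G[:, 0], G[:, 1])


def test_uniform_weights_equal_standardized_grm():
    d = random_design(2)
    Gs = standardized_grm(d).values
    Gw = weighted_grm(d, WeightVector(d=np.ones(d.m))).values
    assert np.array_equal(Gs, Gw) or np.allclose(Gs, Gw, atol=1e-14)


def test_chunk_grms_partition_additively():
    d = random_design(3)
    S = np.arange(0, 20)
    Sbar = np.arange(20, d.m)
    lhs = (S.size * chunk_region_grm(d, S).values
           + Sbar.size * chunk_region_grm(d, Sbar).values)
    assert np.allclose(lhs, d.m * standardized_grm(d).values, atol=1e-10)
    assert chunk_region_grm(d, [0]).values.shape == (d.n, d.n)
    assert np.linalg.matrix_rank(chunk_region_grm(d, [0]).values) == 1
    with pytest.raises(ValueError):
        chunk_region_grm(d, [])


def test_zero_weight_excludes_snp():
    d = random_design(4, n=6, m=2)
    G = weighted_grm(d, WeightVector(d=np.array([2.0, 0.0]))).values
    w1 = d.W[:, 0]
    assert np.allclose(G, np.outer(w1, w1), atol=1e-12)


def test_normalize_trace_examples():
    assert normalize_trace(np.array([9.0, 1.0])).d == pytest.approx([1.8, 0.2])
    assert normalize_trace(np.ones(7)).d == pytest.approx(np.ones(7))
    with pytest.raises(ValueError):
        normalize_trace(np.zeros(3))
    with pytest.raises(ValueError):
        normalize_trace(np.array([-1.0, 2.0]))


def test_am_weight_formula_worked_example():
    # one region of 10 SNPs at half the genetic variance among m=100
    w = am_weight_vector([np.arange(90), np.arange(90, 100)], [0.5, 0.5], 100)
    assert w.d[0] == pytest.approx(0.5556, abs=1e-4)
    assert w.d[95] == pytest.approx(5.0)
    assert w.d.sum() == pytest.approx(100.0, abs=1e-9)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=2, max_size=40)
       .filter(lambda v: sum(v) > 0))
def test_normalize_trace_sums_to_m(raw):
    w = normalize_trace(np.array(raw))
    assert w.d.sum() == pytest.approx(len(raw), rel=1e-12)
    assert (w.d >= 0).all()
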