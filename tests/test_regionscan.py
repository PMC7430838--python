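"""Chunking arithmetic, region formation rules, permutation quantiles,
bootstrap confidence-set selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wblup.grm import build_design, chunk_region_grm
from wblup.regionscan import (Chunk, ChunkScan, ScanConfig, amblup_fit, bootstrap_ci,
                              chunk_scan, form_regions, make_chunks,
                              merge_close_regions, permutation_threshold,
                              select_ci_windows)
from wblup.varcomp import lrt_region

from .conftest import trait_vector
from .test_grm import table_from_calls

MB = 1_000_000


def snp_map(positions, chrom="1"):
    return pd.DataFrame({"snp": [f"s{i}" for i in range(len(positions))],
                         "chrom": chrom, "pos": positions, "allele": "A"})


def test_make_chunks_grid_and_overlap():
    pos = np.arange(50_000, 3 * MB, 100_000)  # spans 0-3 Mb
    chunks = make_chunks(snp_map(pos), ScanConfig())
    assert [c.start for c in chunks] == [0, 500_000, MB, 1_500_000, 2 * MB,
                                         2_500_000]
    # every SNP in at most 2 chunks at 50% overlap
    counts = np.zeros(pos.size)
    for c in chunks:
        counts[c.snp_idx] += 1
    assert counts.max() <= 2


def test_make_chunks_drops_empty_windows():
    pos = np.r_[np.arange(10_000, 400_000, 50_000),
                np.arange(2 * MB + 10_000, 2 * MB + 400_000, 50_000)]
    chunks = make_chunks(snp_map(pos), ScanConfig())
    starts = [c.start for c in chunks]
    # windows falling entirely in the 0.4-2.0 Mb gap are dropped
    assert 500_000 not in starts and 1_000_000 not in starts
    assert all(c.snp_idx.size for c in chunks)


def test_make_chunks_zero_overlap_tiles_disjointly():
    pos = np.arange(10_000, 4 * MB, 97_000)
    chunks = make_chunks(snp_map(pos), ScanConfig(overlap=1e-9))
    counts = np.zeros(pos.size)
    for c in chunks:
        counts[c.snp_idx] += 1
    assert counts.max() == 1


def _scan_from_pvalues(pvals):
    chunks = [Chunk(chrom="1", start=i * 500_000, end=i * 500_000 + MB,
                    snp_idx=np.array([2 * i, 2 * i + 1])) for i in range(len(pvals))]
    # last chunk unique SNPs so the union partitions cleanly
    return ChunkScan(chunks=chunks, pvalues=np.asarray(pvals, float),
                     statistics=np.zeros(len(pvals)))


def test_form_regions_grows_over_thr2_neighbors():
    scan = _scan_from_pvalues([0.5, 0.005, 1e-6, 0.005, 0.5, 0.7])
    rs = form_regions(scan, ScanConfig(), m=12)
    assert rs.K == 1
    assert [c.start for c in rs.regions[0].chunks] == [500_000, MB, 1_500_000]
    rs.validate()


def test_form_regions_no_seed_yields_background_only():
    scan = _scan_from_pvalues([0.5, 0.01, 0.2])
    rs = form_regions(scan, ScanConfig(), m=6)
    assert rs.K == 0
    assert rs.background_idx.size == 6


def test_form_regions_separated_seeds_stay_distinct():
    scan = _scan_from_pvalues([1e-6, 0.5, 0.5, 1e-7, 0.4])
    rs = form_regions(scan, ScanConfig(), m=10)
    assert rs.K == 2


def test_merge_close_regions_by_gap():
    scan = _scan_from_pvalues([1e-6, 0.5, 0.5, 1e-7, 0.4])
    rs = form_regions(scan, ScanConfig(), m=10)
    merged = merge_close_regions(rs, gap_bp=10 * MB)
    assert merged.K == 1
    not_merged = merge_close_regions(rs, gap_bp=100)
    assert not_merged.K == 2


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(1e-9, 1.0), min_size=3, max_size=25))
def test_region_background_partition_invariant(pvals):
    scan = _scan_from_pvalues(pvals)
    rs = form_regions(scan, ScanConfig(), m=2 * len(pvals))
    rs.validate()  # raises if partition broken


def test_select_ci_windows_worked_examples():
    assert select_ci_windows(np.array([1000]), 950).tolist() == [0]
    assert select_ci_windows(np.array([900, 100]), 950).tolist() == [0, 1]
    assert select_ci_windows(np.array([500, 300, 200]), 950).tolist() == [0, 1, 2]
    assert select_ci_windows(np.array([30, 940, 30]), 950).tolist() == [0, 1]


@settings(max_examples=40, deadline=None)
@given(st.lists(st.integers(0, 100), min_size=1, max_size=10),
       st.floats(0.5, 0.99))
def test_ci_selection_monotone_and_contains_mode(counts, level):
    counts = np.array(counts)
    total = counts.sum()
    lo = select_ci_windows(counts, 0.5 * total)
    hi = select_ci_windows(counts, level * total if level > 0.5 else 0.5 * total)
    assert int(np.argmax(counts)) in lo
    if level >= 0.5:
        assert set(lo) <= set(hi)


def test_permutation_quantile_matches_type7_oracle():
    minima = np.arange(1, 1001) / 1000.0
    h = 0.05 * (len(minima) - 1)
    lo = int(np.floor(h))
    oracle = minima[lo] + (h - lo) * (minima[lo + 1] - minima[lo])
    assert np.quantile(minima, 0.05) == pytest.approx(oracle, rel=1e-12)


def test_permutation_threshold_deterministic_under_seed(bundle, design, split):
    tr, _ = split
    y = trait_vector(bundle, "poly", tr)
    cfg = ScanConfig(n_permutations=3, seed=7, chunk_size=4 * MB)
    a = permutation_threshold(y, design, cfg, train_idx=tr)
    b = permutation_threshold(y, design, cfg, train_idx=tr)
    assert a.threshold == b.threshold
    assert np.array_equal(a.min_pvalues, b.min_pvalues)
    assert a.threshold == pytest.approx(np.quantile(a.min_pvalues, 0.05))


def test_fast_scan_engine_matches_dense_reml():
    """The eigendecomposition/Woodbury scan path maximizes the same REML
    objective as the dense AI-REML route, chunk by chunk."""
    rng = np.random.default_rng(33)
    calls = rng.binomial(2, rng.uniform(0.2, 0.8, 60), size=(80, 60))
    pos = np.sort(rng.choice(np.arange(1, 4 * MB), 60, replace=False))
    g = table_from_calls(calls)
    g.snps["pos"] = pos
    d = build_design(g)
    y = d.W[:, 7] * 0.5 + rng.normal(size=80)
    cfg = ScanConfig()
    scan = chunk_scan(y, d, cfg)
    W, m = d.W, d.m
    S = W @ W.T
    for ch, stat in zip(scan.chunks, scan.statistics):
        Wc = W[:, ch.snp_idx]
        Sc = Wc @ Wc.T
        mc = ch.snp_idx.size
        dense = lrt_region(y, (S - Sc) / (m - mc), Sc / mc, tol=1e-8,
                           max_iter=200)
        assert stat == pytest.approx(dense.statistic, abs=2e-3)


def test_single_chunk_scan_equals_direct_lrt():
    rng = np.random.default_rng(21)
    calls = rng.binomial(2, rng.uniform(0.2, 0.8, 30), size=(60, 30))
    g = table_from_calls(calls)  # all positions within one chunk
    d = build_design(g)
    y = rng.normal(size=60)
    scan = chunk_scan(y, d, ScanConfig(), train_idx=np.arange(60))
    assert len(scan.chunks) == 1
    direct = lrt_region(y, None, chunk_region_grm(d, np.arange(30)).values)
    assert scan.pvalues[0] == pytest.approx(direct.pvalue, rel=1e-6)


def test_chunk_scan_finds_planted_region(bundle, design, split):
    tr, _ = split
    y = trait_vector(bundle, "qtl", tr)
    cfg = ScanConfig(chunk_size=2 * MB, seed=1)
    scan = chunk_scan(y, design, cfg, train_idx=tr)
    best = scan.chunks[scan.min_index()]
    reg = bundle.truth["qtl"].regions[0]
    qtl_pos = int(design.snps.loc[reg["qtl_snps"][0], "pos"])
    assert best.chrom == reg["chrom"]
    assert best.start <= qtl_pos < best.end


def test_amblup_weights_trace_and_degenerate_uniform(bundle, design, split):
    tr, _ = split
    y = trait_vector(bundle, "poly", tr)
    scan = _scan_from_pvalues([0.5, 0.3])
    rs = form_regions(scan, ScanConfig(), m=design.m)
    fit, w = amblup_fit(y, design, rs, train_idx=tr)
    assert np.allclose(w.d, 1.0)  # K=0 -> uniform weights
    y2 = trait_vector(bundle, "qtl", tr)
    cfg = ScanConfig(chunk_size=2 * MB, thr1=0.05, thr2=0.2, seed=1)
    scan2 = chunk_scan(y2, design, cfg, train_idx=tr)
    rs2 = form_regions(scan2, cfg, m=design.m)
    if rs2.K:
        _, w2 = amblup_fit(y2, design, rs2, train_idx=tr)
        assert w2.d.sum() == pytest.approx(design.m, rel=1e-12)


def test_bootstrap_ci_on_planted_region(bundle, design, split):
    tr, _ = split
    y = trait_vector(bundle, "qtl", tr)
    cfg = ScanConfig(chunk_size=2 * MB, thr1=0.05, thr2=0.1, n_bootstrap=25,
                     seed=3)
    scan = chunk_scan(y, design, cfg, train_idx=tr)
    rs = form_regions(scan, cfg, m=design.m)
    assert rs.K >= 1
    region = max(rs.regions, key=lambda r: r.m_k)
    ci = bootstrap_ci(y, design, region, cfg, train_idx=tr)
    assert ci.flag_counts.sum() == cfg.n_bootstrap
    assert int(np.argmax(ci.flag_counts)) in ci.selected
    assert ci.snp_idx.size <= region.m_k  # CI never exceeds the thr2 region
    assert ci.flag_counts[ci.selected].sum() >= cfg.ci_level * cfg.n_bootstrap
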