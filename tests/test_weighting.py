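"""WPIP window selection, iterative nonlinear weighting, BRPV weights."""

import numpy as np
import pytest

from wblup.bayes import PosteriorSummary
from wblup.gblup import gblup_predict
from wblup.grm import WeightVector, build_design, weighted_grm
from wblup.varcomp import reml_fit
from wblup.weighting import (brpv_weights, iw_gblup, nonlinear_raw_weights,
                             wpip_select, wpip_weights)

from .conftest import trait_vector  # noqa: F401 (fixture helpers)


def summary_from_pips(pips):
    pips = np.asarray(pips, dtype=float)
    return PosteriorSummary(pip=pips, beta_mean=np.zeros(pips.size),
                            post_var=np.zeros(pips.size), mu=0.0, model="bslmm")


def test_wpip_single_dominant_snp_window():
    pips = np.full(25, 0.002)
    pips[7] = 0.96
    sel = wpip_select(summary_from_pips(pips))
    assert len(sel) == 1
    w = sel[0]
    assert w.cumulative_pip == pytest.approx(1.008)
    # 0.96 >= 0.95 * 1.008, so the dominant SNP alone is retained
    assert w.selected_idx.tolist() == [7]


def test_wpip_subthreshold_window_not_selected():
    assert wpip_select(summary_from_pips(np.full(25, 0.4 / 25))) == []


def test_wpip_uniform_pips_keep_24_of_25():
    sel = wpip_select(summary_from_pips(np.full(25, 0.04)))
    assert len(sel) == 1
    assert sel[0].selected_idx.size == 24  # 23*0.04 < 0.95 <= 24*0.04


def test_wpip_windows_break_at_chromosomes():
    import pandas as pd
    pips = np.zeros(40)
    pips[19] = 0.9  # last SNP of chromosome 1
    snps = pd.DataFrame({"chrom": ["1"] * 20 + ["2"] * 20})
    sel = wpip_select(summary_from_pips(pips), snps=snps)
    assert len(sel) == 1
    assert sel[0].snp_idx.max() == 19  # window confined to chromosome 1


def test_wpip_selection_invariant_to_failing_windows():
    pips = np.r_[np.full(25, 0.04), np.full(25, 0.001)]
    base = wpip_select(summary_from_pips(pips))
    noisier = pips.copy()
    noisier[25:] = 0.015  # still below the 0.5 window threshold
    again = wpip_select(summary_from_pips(noisier))
    assert [w.selected_idx.tolist() for w in base] == \
        [w.selected_idx.tolist() for w in again]


def test_wpip_weights_empty_selection_is_uniform(design):
    res = wpip_weights(np.zeros(design.n) + np.arange(design.n) * 0.01,
                       design, [])
    assert np.allclose(res.weights.d, 1.0)


def test_wpip_weights_upweight_planted_qtl(bundle, design, split):
    tr, _ = split
    y = trait_vector(bundle, "qtl", tr)
    qtl = bundle.truth["qtl"].regions[0]["qtl_snps"]
    pips = np.full(design.m, 0.001)
    pips[qtl] = 0.95
    sel = wpip_select(summary_from_pips(pips))
    res = wpip_weights(y, design, sel, train_idx=tr)
    assert res.weights.d.sum() == pytest.approx(design.m, rel=1e-12)
    assert res.weights.d[qtl].mean() > 1.0


def test_nonlinear_weight_map_worked_points():
    rng = np.random.default_rng(0)
    beta = rng.normal(size=2000)
    beta = (beta - beta.mean()) / beta.std()
    beta[0], beta[1] = 2.0 * beta.std(), 12.0 * beta.std()
    raw = nonlinear_raw_weights(beta, cap=2.6)
    sd = beta.std()
    assert raw[0] == pytest.approx(1.125 ** (abs(beta[0]) / sd - 2))
    assert raw[1] == pytest.approx(2.6, abs=1e-9)  # ceiling binds at 12 sd
    # equal-magnitude effects end up with uniform weights after the trace fill
    from wblup.weighting import _cap_and_fill
    equal = nonlinear_raw_weights(np.full(10, 0.3), cap=2.6)
    assert np.allclose(_cap_and_fill(equal, 2.6, 10), 1.0)
    alternating = nonlinear_raw_weights(np.tile([0.3, -0.3], 5), cap=2.6)
    assert np.allclose(_cap_and_fill(alternating, 2.6, 10), 1.0)


def test_iw_gblup_cap_one_reproduces_standardized_gblup(bundle, design, split):
    tr, va = split
    y = trait_vector(bundle, "qtl", tr)
    res = iw_gblup(y, design, train_idx=tr, n_iter=3, cap=1.0)
    assert np.allclose(res.weights.d, 1.0)
    G = weighted_grm(design, res.weights)
    fit = reml_fit(y, [G.values[np.ix_(tr, tr)]])
    pred_w = gblup_predict(y, [G], fit.vc, train_idx=tr, val_idx=va)
    Gs = weighted_grm(design, WeightVector(d=np.ones(design.m)))
    pred_s = gblup_predict(y, [Gs], fit.vc, train_idx=tr, val_idx=va)
    assert np.allclose(pred_w.ghat, pred_s.ghat)


def test_iw_gblup_trace_and_cap_respected(bundle, design, split):
    tr, _ = split
    y = trait_vector(bundle, "qtl", tr)
    res = iw_gblup(y, design, train_idx=tr, n_iter=2)
    d = res.weights.d
    assert d.sum() == pytest.approx(design.m, rel=1e-9)
    assert d.max() <= 2.6 + 1e-9
    assert len(res.meta["history"]) == 3  # initial + 2 iterations


def test_brpv_weights_proportional_and_guarded():
    eps = 1e-5
    s = PosteriorSummary(pip=np.zeros(2), beta_mean=np.zeros(2),
                         post_var=np.array([9 * eps, eps]), mu=0.0, model="bayesr")
    res = brpv_weights(s)
    assert res.weights.d == pytest.approx([1.8, 0.2])
    s.post_var = np.ones(5)
    assert np.allclose(brpv_weights(s).weights.d, 1.0)
    s.post_var = np.zeros(5)
    with pytest.raises(ValueError):
        brpv_weights(s)
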