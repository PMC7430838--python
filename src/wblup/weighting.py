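"""Strategies converting association evidence into per-SNP GRM weights.

* WPIP: 25-SNP windows ranked by cumulative posterior inclusion probability;
  windows above 0.5 are kept, reduced to the smallest PIP-ranked SNP subset
  carrying 95% of the window PIP, and each retained window's variance is
  estimated by multi-kernel REML and turned into weights.
* IW-GBLUP: iterative reweighting from back-solved SNP effects with the
  nonlinearA map d_j = 1.125**(|beta_j|/sd(beta) - 2), the weight capped at
  2.6 and the trace renormalized to m every iteration.
* BRPV: weights proportional to BayesR posterior SNP variances, trace m.

Every result honours the trace contract: sum of weights = m exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes import PosteriorSummary
from .gblup import backsolve_snp_effects, gblup_predict
from .grm import (GenotypeDesign, WeightVector, am_weight_vector,
                  normalize_trace, weighted_grm)
from .varcomp import reml_fit

__all__ = [
    "WindowPip",
    "WeightingResult",
    "nonlinear_raw_weights",
    "wpip_select",
    "wpip_weights",
    "iw_gblup",
    "brpv_weights",
]

NONLINEAR_BASE = 1.125  # classic "nonlinearA" weight base


def nonlinear_raw_weights(beta: np.ndarray, cap: float) -> np.ndarray:
    """NonlinearA map: d_j = 1.125**(|beta_j|/sd(beta) - 2), the exponent
    argument capped so the raw weight never exceeds ``cap``."""
    beta = np.asarray(beta, dtype=float)
    sd = float(np.std(beta))
    if sd <= 1e-12 * max(float(np.abs(beta).max()), 1e-300):
        return np.ones(beta.size)  # no spread in effects: no reweighting
    t_cap = 2.0 + np.log(cap) / np.log(NONLINEAR_BASE)
    t = np.minimum(np.abs(beta) / sd, t_cap)
    return NONLINEAR_BASE ** (t - 2.0)


def _cap_and_fill(raw: np.ndarray, cap: float, m: int) -> np.ndarray:
    """Trace-m normalization under a hard per-SNP ceiling.

    Uncapped weights are rescaled proportionally to fill the trace left by
    the capped ones; SNPs pushed over the ceiling by the rescale are capped
    and the rest refilled (water-filling). ``cap = 1`` forces exactly uniform
    weights, since no weight may exceed the mean.
    """
    if cap < 1.0:
        raise ValueError("weight cap below 1 cannot satisfy the trace contract")
    d = np.minimum(raw, cap).astype(float)
    capped = np.zeros(d.size, dtype=bool)
    for _ in range(d.size):
        free = ~capped
        remaining = m - cap * capped.sum()
        s = d[free].sum()
        if s <= 0:
            d[free] = remaining / free.sum()
        else:
            d[free] *= remaining / s
        over = free & (d > cap)
        if not over.any():
            break
        d[over] = cap
        capped |= over
    return d


@dataclass
class WindowPip:
    index: int
    snp_idx: np.ndarray         # all SNPs in the window (panel order)
    cumulative_pip: float
    selected_idx: np.ndarray    # retained high-PIP subset


@dataclass
class WeightingResult:
    weights: WeightVector
    strategy: str
    meta: dict = field(default_factory=dict)


def wpip_select(
    summary: PosteriorSummary,
    snps=None,
    window_size: int = 25,
    window_threshold: float = 0.5,
    mass: float = 0.95,
) -> list:
    """Select 25-SNP windows by cumulative PIP and prune them to high-PIP SNPs.

    Windows are non-overlapping in panel order and never span two chromosomes
    (``snps`` map optional; without it the panel is treated as one
    chromosome). Within a kept window, SNPs are ranked by PIP (ties leftmost)
    and the smallest prefix reaching ``mass`` of the window PIP is retained.
    """
    pip = np.asarray(summary.pip, dtype=float)
    m = pip.size
    if snps is not None:
        chrom = np.asarray(snps["chrom"])
        breaks = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        segments = np.split(np.arange(m), breaks)
    else:
        segments = [np.arange(m)]

    windows: list[WindowPip] = []
    w_i = 0
    for seg in segments:
        for s in range(0, seg.size, window_size):
            idx = seg[s: s + window_size]
            total = float(pip[idx].sum())
            if total > window_threshold:
                order = idx[np.lexsort((idx, -pip[idx]))]  # PIP desc, leftmost first
                csum = np.cumsum(pip[order])
                k = int(np.searchsorted(csum, mass * total - 1e-12) + 1)
                windows.append(WindowPip(index=w_i, snp_idx=idx,
                                         cumulative_pip=total,
                                         selected_idx=np.sort(order[:k])))
            w_i += 1
    return windows


def wpip_weights(
    y_train,
    design: GenotypeDesign,
    selection: list,
    train_idx=None,
    max_iter: int = 100,
) -> WeightingResult:
    """REML variance per selected window, converted to trace-m weights.

    One kernel per selected window (its retained SNPs) plus a background
    kernel over every other SNP; weights follow the AM rule
    ``d = (sigma_k^2/m_k) / (sigma_T^2/m)``. An empty selection yields
    uniform weights (standardized GBLUP).
    """
    m = design.m
    if not selection:
        return WeightingResult(weights=WeightVector(d=np.ones(m), provenance="wpip"),
                               strategy="wpip", meta={"n_windows": 0})
    y = np.asarray(y_train, dtype=float)
    tr = np.arange(design.n) if train_idx is None else np.asarray(train_idx, int)
    W = design.W[tr]
    groups = [w.selected_idx for w in selection]
    retained = np.concatenate(groups)
    bg = np.setdiff1d(np.arange(m), retained)
    kernel_groups = ([bg] if bg.size else []) + groups
    kernels = [W[:, idx] @ W[:, idx].T / idx.size for idx in kernel_groups]
    fit = reml_fit(y, kernels, max_iter=max_iter)

    weights = am_weight_vector(kernel_groups, fit.vc.sigma2, m, provenance="wpip")
    return WeightingResult(
        weights=weights, strategy="wpip",
        meta={"n_windows": len(selection),
              "n_retained_snps": int(retained.size),
              "sigma2": fit.vc.sigma2.tolist(), "h2": fit.vc.h2})


def iw_gblup(
    y_train,
    design: GenotypeDesign,
    train_idx=None,
    n_iter: int = 10,
    cap: float = 2.6,
    max_reml_iter: int = 100,
) -> WeightingResult:
    """Iterative SNP weighting from back-solved GBLUP effects.

    Each iteration refits variance components on the current weighted GRM,
    back-solves SNP effects, maps |beta|/sd(beta) through the nonlinearA
    weight ``1.125**(t - 2)`` with the weight capped at ``cap``, and
    renormalizes the trace to m. ``cap = 1`` makes reweighting impossible and
    reproduces the standardized GBLUP exactly.
    """
    y = np.asarray(y_train, dtype=float)
    tr = np.arange(design.n) if train_idx is None else np.asarray(train_idx, int)
    m = design.m
    d = np.ones(m)
    history = [d.copy()]
    fit = None
    for _ in range(n_iter):
        w = WeightVector(d=d, provenance="iterative")
        G = weighted_grm(design, w)
        init = None if fit is None else np.r_[fit.vc.sigma2, fit.vc.sigma2_e]
        fit = reml_fit(y, [G.values[np.ix_(tr, tr)]], init=init,
                       max_iter=max_reml_iter)
        pred = gblup_predict(y, [G], fit.vc, train_idx=tr,
                             samples=design.samples)
        beta = backsolve_snp_effects(pred, design, w).beta
        if float(np.std(beta)) == 0.0:
            d = np.ones(m)
            history.append(d.copy())
            break
        d = _cap_and_fill(nonlinear_raw_weights(beta, cap), cap, m)
        history.append(d.copy())
    weights = WeightVector(d=d, provenance="iterative")
    return WeightingResult(weights=weights, strategy="iw-gblup",
                           meta={"n_iter": n_iter, "cap": cap,
                                 "history": history,
                                 "h2": fit.vc.h2 if fit is not None else None})


def brpv_weights(summary: PosteriorSummary, m: int | None = None) -> WeightingResult:
    """Weights proportional to BayesR posterior SNP variances, trace m."""
    pv = np.asarray(summary.post_var, dtype=float)
    if pv.sum() == 0:
        raise ValueError("all-zero posterior SNP variance")
    m = pv.size if m is None else m
    weights = normalize_trace(pv, provenance="bayesr-posterior", m=m)
    return WeightingResult(weights=weights, strategy="brpv",
                           meta={"model": summary.model})
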