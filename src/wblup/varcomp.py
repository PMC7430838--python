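"""REML variance-component estimation and the region likelihood-ratio test.

The model is ``y = X b + sum_k g_k + e`` with ``g_k ~ N(0, G_k sigma_k^2)``
and ``e ~ N(0, I sigma_e^2)`` (X defaults to the intercept, matching trait
deviations already corrected for fixed effects).

Estimation is average-information (AI) REML with EM fallback steps whenever
an AI proposal leaves the parameter space or decreases the restricted
likelihood; components are constrained to be non-negative by an active set
that pins them at zero. Likelihoods are evaluated through dense Cholesky
factorizations of ``V = sum_k sigma_k^2 G_k + sigma_e^2 I``, which is the
right tool at the few-thousand-individual scale this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import chi2

__all__ = [
    "VarianceComponents",
    "RemlFit",
    "LrtResult",
    "reml_loglik",
    "reml_fit",
    "lrt_region",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceComponents:
    sigma2: np.ndarray          # genetic variances, one per kernel
    sigma2_e: float

    def __post_init__(self) -> None:
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))

    @property
    def sigma2_T(self) -> float:
        return float(self.sigma2.sum())

    @property
    def h2(self) -> float:
        tot = self.sigma2_T + self.sigma2_e
        return float(self.sigma2_T / tot) if tot > 0 else 0.0


@dataclass
class RemlFit:
    vc: VarianceComponents
    loglik: float
    beta: np.ndarray            # fixed effects; beta[0] is the intercept
    converged: bool
    n_iter: int
    se: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def mu(self) -> float:
        return float(self.beta[0])


@dataclass
class LrtResult:
    statistic: float
    pvalue: float
    df_convention: str = "mixture"  # 1/2 chi2_0 + 1/2 chi2_1 boundary mixture


def _as_matrix(k) -> np.ndarray:
    return k.values if hasattr(k, "values") and not isinstance(k, np.ndarray) else np.asarray(k, float)


def _v_matrix(kernels, theta, n) -> np.ndarray:
    V = np.zeros((n, n))
    for G, s2 in zip(kernels, theta[:-1]):
        if s2 != 0.0:
            V += s2 * G
    V[np.diag_indices(n)] += theta[-1]
    return V


def _reml_pieces(y, X, kernels, theta):
    """Return (loglik, P, Py) for parameter vector theta = (sigma2..., sigma2_e)."""
    n = y.shape[0]
    V = _v_matrix(kernels, theta, n)
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf, None, None
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf, None, None
    XtViX_inv = np.linalg.inv(XtViX)
    P = Vi - ViX @ XtViX_inv @ ViX.T
    Py = P @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py) + (n - X.shape[1]) * _LOG2PI)
    return ll, P, Py


def reml_loglik(y, kernels, theta, X=None) -> float:
    """Restricted log-likelihood at ``theta = (sigma2_1..sigma2_K, sigma2_e)``."""
    y = np.asarray(y, dtype=float)
    X = np.ones((y.size, 1)) if X is None else np.asarray(X, dtype=float)
    ks = [_as_matrix(k) for k in kernels]
    ll, _, _ = _reml_pieces(y, X, ks, np.asarray(theta, dtype=float))
    return ll


def reml_fit(
    y,
    kernels,
    X=None,
    max_iter: int = 100,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
) -> RemlFit:
    """AI-REML fit of K genetic variance components plus a residual.

    ``init`` optionally warm-starts the parameter vector
    ``(sigma2_1..sigma2_K, sigma2_e)``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ks = [_as_matrix(k) for k in kernels]
    K = len(ks)
    if n <= X.shape[1]:
        raise ValueError("more fixed effects than observations")
    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("phenotype has zero variance")
    for G in ks:
        if G.shape != (n, n):
            raise ValueError("kernel dimensions must match the phenotype vector")

    floor = 1e-10 * vary
    if init is not None:
        theta = np.maximum(np.asarray(init, dtype=float).copy(), floor)
        if theta.size != K + 1:
            raise ValueError("init must have one entry per kernel plus residual")
    else:
        theta = np.r_[np.full(K, 0.5 * vary / max(K, 1)), 0.5 * vary]

    ll, P, Py = _reml_pieces(y, X, ks, theta)
    if not np.isfinite(ll):
        raise ValueError("non-finite restricted likelihood at the starting values")

    converged = False
    ai = None
    it = 0
    for it in range(1, max_iter + 1):
        # score and AI ingredients at current theta
        GPy = [G @ Py for G in ks] + [Py]
        score = np.empty(K + 1)
        for k in range(K + 1):
            trPG = float(np.sum(P * ks[k])) if k < K else float(np.trace(P))
            score[k] = -0.5 * (trPG - float(Py @ GPy[k]))
        PGPy = [P @ v for v in GPy]
        ai = 0.5 * np.array([[float(GPy[a] @ PGPy[b]) for b in range(K + 1)]
                             for a in range(K + 1)])

        active = theta > floor * 2
        active |= score > 0  # pinned components with positive gradient re-enter
        idx = np.flatnonzero(active)

        def em_step():
            nt = theta.copy()
            for k in range(K + 1):
                trPG = float(np.sum(P * ks[k])) if k < K else float(np.trace(P))
                nt[k] = theta[k] + theta[k] ** 2 * (float(Py @ GPy[k]) - trPG) / n
            return np.maximum(nt, floor)

        proposal = None
        if it > 1 and idx.size:
            try:
                delta = np.linalg.solve(ai[np.ix_(idx, idx)], score[idx])
                cand = theta.copy()
                cand[idx] = theta[idx] + delta
                cand[~active] = floor
                proposal = cand
            except np.linalg.LinAlgError:
                proposal = None

        accepted = False
        if proposal is not None:
            step = proposal - theta
            for _ in range(6):  # step-halving
                cand = np.maximum(theta + step, floor)
                ll_new, P_new, Py_new = _reml_pieces(y, X, ks, cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                    accepted = True
                    break
                step *= 0.5
        if not accepted:
            cand = em_step()
            ll_new, P_new, Py_new = _reml_pieces(y, X, ks, cand)
            if not np.isfinite(ll_new) or ll_new < ll - 1e-8:
                # EM should not decrease the likelihood; treat as converged
                converged = True
                break

        rel = np.max(np.abs(cand - theta) / (np.abs(theta) + vary * 1e-8))
        dll = ll_new - ll
        theta, ll, P, Py = cand, ll_new, P_new, Py_new
        if rel < tol or abs(dll) < 1e-8:
            converged = True
            break

    theta = np.where(theta <= floor * 2, 0.0, theta)
    ll, P, Py = _reml_pieces(y, X, ks, np.maximum(theta, floor))
    # GLS fixed effects at the optimum
    V = _v_matrix(kernels=ks, theta=np.maximum(theta, floor), n=n)
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    ViX = linalg.cho_solve((c, low), X, check_finite=False)
    Viy = linalg.cho_solve((c, low), y, check_finite=False)
    beta = np.linalg.solve(X.T @ ViX, X.T @ Viy)

    se = None
    if ai is not None:
        try:
            se = np.sqrt(np.diag(np.linalg.inv(ai)))
        except np.linalg.LinAlgError:
            se = None
    vc = VarianceComponents(sigma2=theta[:K], sigma2_e=float(theta[K]))
    return RemlFit(vc=vc, loglik=float(ll), beta=beta, converged=converged,
                   n_iter=it, se=se)


def lrt_region(
    y,
    background,
    region,
    X=None,
    df_convention: str = "mixture",
    null_init: np.ndarray | None = None,
    **reml_kw,
) -> LrtResult:
    """Boundary LRT for a region variance component on top of a background GRM.

    Null: background kernel only. Full: background + region kernels. Under the
    null the statistic follows the boundary mixture 1/2 chi2_0 + 1/2 chi2_1
    (default) or, optionally, a plain chi2_1. ``null_init`` warm-starts the
    null fit (used by genome scans).
    """
    bg = [] if background is None else [background]
    if null_init is not None and len(bg) == 0:
        null_init = np.asarray(null_init)[-1:]
    null = reml_fit(y, bg, X=X, init=null_init, **reml_kw)
    init = np.r_[null.vc.sigma2, 0.05 * (null.vc.sigma2_T + null.vc.sigma2_e),
                 null.vc.sigma2_e]
    full = reml_fit(y, bg + [region], X=X, init=init, **reml_kw)
    stat = 2.0 * (full.loglik - null.loglik)
    if stat < 0:
        stat = 0.0
    if stat == 0.0:
        p = 1.0
    elif df_convention == "mixture":
        p = 0.5 * float(chi2.sf(stat, df=1))
    elif df_convention == "chi2":
        p = float(chi2.sf(stat, df=1))
    else:
        raise ValueError(f"unknown df convention: {df_convention}")
    return LrtResult(statistic=float(stat), pvalue=p, df_convention=df_convention)
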