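"""Gibbs samplers for two Bayesian SNP-effect mixture models.

BSLMM-style two-component model: on standardized genotypes W,

    y = 1 mu + W beta + e,
    beta_j ~ pi N(0, sigma_a^2 + sigma_b^2) + (1 - pi) N(0, sigma_b^2),

so every SNP carries at least a small polygenic effect and a fraction pi
additionally a large one. The posterior inclusion probability (PIP) of a SNP
is the share of retained samples in which it occupies the large class.

BayesR-style four-component model:

    beta_j ~ pi_1 N(0, 0) + pi_2 N(0, 1e-4 sigma_g^2)
           + pi_3 N(0, 1e-3 sigma_g^2) + pi_4 N(0, 1e-2 sigma_g^2),

with sigma_g^2 resampled each iteration so class variances track it. The
per-SNP posterior variance is the average over retained iterations of the
class variance the SNP occupies at that iteration (a SNP sitting in class 2
with sigma_g^2 = 1 contributes 1e-4), which is the quantity the BRPV
weighting strategy consumes.

Both samplers are single-site Gibbs with conjugate updates (scaled-inverse
chi-square variances, Beta/Dirichlet proportions) and are deterministic under
their seed. Inner loops are JIT-compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .gblup import Prediction
from .grm import GenotypeDesign

__all__ = [
    "BslmmConfig",
    "BayesrConfig",
    "PosteriorSummary",
    "bslmm_sample",
    "bayesr_sample",
    "predict_from_posterior",
]

BAYESR_CLASS_FRACTIONS = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class BslmmConfig:
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 1
    pi_init: float = 0.01
    pi_fixed: float | None = None   # freeze pi (0 degenerates to ridge/GBLUP)
    pi_prior_b: float | None = None  # Beta(1, b) prior; default m/100

    def __post_init__(self) -> None:
        if not 0 < self.burn_in < self.n_iter:
            raise ValueError("need 0 < burn_in < n_iter")


@dataclass
class BayesrConfig:
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 1
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.burn_in < self.n_iter:
            raise ValueError("need 0 < burn_in < n_iter")


@dataclass
class PosteriorSummary:
    pip: np.ndarray             # large-effect (BSLMM) / nonzero (BayesR) frequency
    beta_mean: np.ndarray       # posterior mean SNP effect, standardized scale
    post_var: np.ndarray        # posterior mean per-SNP effect variance
    mu: float
    model: str
    trace: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if ((self.pip < -1e-12) | (self.pip > 1 + 1e-12)).any():
            raise ValueError("PIP outside [0,1]")
        if (self.post_var < 0).any():
            raise ValueError("negative posterior variance")


@njit(cache=True)
def _bslmm_chain(W, y, n_iter, burn, thin, pi_init, pi_fixed, pi_a, pi_b, seed):
    np.random.seed(seed)
    n, m = W.shape
    wtw = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += W[i, j] * W[i, j]
        wtw[j] = s
    vy = np.var(y)
    mu = np.mean(y)
    beta = np.zeros(m)
    large = np.zeros(m, dtype=np.uint8)
    v_small = 0.5 * vy / m
    v_large = v_small + 0.1 * vy
    sige = 0.5 * vy
    pi = pi_fixed if pi_fixed >= 0.0 else pi_init
    r = y - mu

    nu0 = 2.0
    s0_small = 0.5 * vy / m
    s0_large = 0.1 * vy
    s0_e = 0.5 * vy

    n_keep = (n_iter - burn + thin - 1) // thin
    pip = np.zeros(m)
    bmean = np.zeros(m)
    pvar = np.zeros(m)
    trace = np.zeros((n_keep, 5))  # pi, v_small, v_large, sige, mu
    mu_acc = 0.0
    kept = 0

    for it in range(n_iter):
        # intercept: conjugate normal around the mean of (r + mu)
        rm = 0.0
        for i in range(n):
            rm += r[i]
        rm = rm / n + mu
        mu_new = np.random.normal(rm, np.sqrt(sige / n))
        for i in range(n):
            r[i] += mu - mu_new
        mu = mu_new

        # SNP effects and class indicators
        n_large = 0
        for j in range(m):
            bj = beta[j]
            if bj != 0.0:
                for i in range(n):
                    r[i] += W[i, j] * bj
            rhs = 0.0
            for i in range(n):
                rhs += W[i, j] * r[i]
            # class log-marginals
            prec_s = wtw[j] / sige + 1.0 / v_small
            prec_l = wtw[j] / sige + 1.0 / v_large
            q = rhs / sige
            log_s = np.log(1.0 - pi + 1e-300) - 0.5 * np.log(v_small * prec_s) \
                + 0.5 * q * q / prec_s
            log_l = np.log(pi + 1e-300) - 0.5 * np.log(v_large * prec_l) \
                + 0.5 * q * q / prec_l
            mx = max(log_s, log_l)
            p_l = np.exp(log_l - mx) / (np.exp(log_s - mx) + np.exp(log_l - mx))
            if np.random.random() < p_l:
                large[j] = 1
                n_large += 1
                prec = prec_l
            else:
                large[j] = 0
                prec = prec_s
            bj = np.random.normal(q / prec, np.sqrt(1.0 / prec))
            beta[j] = bj
            for i in range(n):
                r[i] -= W[i, j] * bj

        # variance components (scaled-inverse-chi-square updates)
        ss_s = 0.0
        k_s = 0
        ss_l = 0.0
        k_l = 0
        for j in range(m):
            if large[j] == 1:
                ss_l += beta[j] * beta[j]
                k_l += 1
            else:
                ss_s += beta[j] * beta[j]
                k_s += 1
        v_small = (nu0 * s0_small + ss_s) / np.random.chisquare(nu0 + k_s)
        v_large = (nu0 * s0_large + ss_l) / np.random.chisquare(nu0 + k_l)
        if v_large < v_small * 1.001:
            v_large = v_small * 1.001
        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        sige = (nu0 * s0_e + sse) / np.random.chisquare(nu0 + n)
        if pi_fixed < 0.0:
            pi = np.random.beta(pi_a + n_large, pi_b + m - n_large)
        else:
            pi = pi_fixed

        if it >= burn and (it - burn) % thin == 0:
            for j in range(m):
                pip[j] += large[j]
                bmean[j] += beta[j]
                pvar[j] += v_large if large[j] == 1 else v_small
            trace[kept, 0] = pi
            trace[kept, 1] = v_small
            trace[kept, 2] = v_large
            trace[kept, 3] = sige
            trace[kept, 4] = mu
            mu_acc += mu
            kept += 1

    return pip / kept, bmean / kept, pvar / kept, trace[:kept], mu_acc / kept


@njit(cache=True)
def _bayesr_chain(W, y, n_iter, burn, thin, alpha0, cfrac, seed):
    np.random.seed(seed)
    n, m = W.shape
    wtw = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += W[i, j] * W[i, j]
        wtw[j] = s
    vy = np.var(y)
    mu = np.mean(y)
    beta = np.zeros(m)
    cls = np.zeros(m, dtype=np.int8)
    sigg = 0.5 * vy
    sige = 0.5 * vy
    pi = np.array([0.95, 0.02, 0.02, 0.01])
    r = y - mu

    nu0 = 4.0
    s0_g = 0.5 * vy
    s0_e = 0.5 * vy

    n_keep = (n_iter - burn + thin - 1) // thin
    pip = np.zeros(m)
    bmean = np.zeros(m)
    pvar = np.zeros(m)
    trace = np.zeros((n_keep, 7))  # pi1..4, sigma_g2, sigma_e2, mu
    mu_acc = 0.0
    kept = 0
    logml = np.empty(4)

    for it in range(n_iter):
        mu_new = np.random.normal(np.mean(r) + mu, np.sqrt(sige / n))
        for i in range(n):
            r[i] += mu - mu_new
        mu = mu_new

        counts = np.zeros(4)
        for j in range(m):
            bj = beta[j]
            if bj != 0.0:
                for i in range(n):
                    r[i] += W[i, j] * bj
            rhs = 0.0
            for i in range(n):
                rhs += W[i, j] * r[i]
            q = rhs / sige
            logml[0] = np.log(pi[0] + 1e-300)
            for k in range(1, 4):
                v = cfrac[k] * sigg
                prec = wtw[j] / sige + 1.0 / v
                logml[k] = np.log(pi[k] + 1e-300) - 0.5 * np.log(v * prec) \
                    + 0.5 * q * q / prec
            mx = logml[0]
            for k in range(1, 4):
                if logml[k] > mx:
                    mx = logml[k]
            tot = 0.0
            for k in range(4):
                logml[k] = np.exp(logml[k] - mx)
                tot += logml[k]
            u = np.random.random() * tot
            acc = 0.0
            kk = 3
            for k in range(4):
                acc += logml[k]
                if u <= acc:
                    kk = k
                    break
            cls[j] = kk
            counts[kk] += 1.0
            if kk == 0:
                beta[j] = 0.0
            else:
                v = cfrac[kk] * sigg
                prec = wtw[j] / sige + 1.0 / v
                bj = np.random.normal(q / prec, np.sqrt(1.0 / prec))
                beta[j] = bj
                for i in range(n):
                    r[i] -= W[i, j] * bj

        # sigma_g^2 given effects and classes
        ss = 0.0
        k_nz = 0
        for j in range(m):
            if cls[j] > 0:
                ss += beta[j] * beta[j] / cfrac[cls[j]]
                k_nz += 1
        sigg = (nu0 * s0_g + ss) / np.random.chisquare(nu0 + k_nz)
        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        sige = (nu0 * s0_e + sse) / np.random.chisquare(nu0 + n)
        # Dirichlet via gammas
        tot = 0.0
        for k in range(4):
            pi[k] = np.random.gamma(alpha0[k] + counts[k], 1.0)
            tot += pi[k]
        for k in range(4):
            pi[k] /= tot

        if it >= burn and (it - burn) % thin == 0:
            for j in range(m):
                if cls[j] > 0:
                    pip[j] += 1.0
                bmean[j] += beta[j]
                pvar[j] += cfrac[cls[j]] * sigg
            for k in range(4):
                trace[kept, k] = pi[k]
            trace[kept, 4] = sigg
            trace[kept, 5] = sige
            trace[kept, 6] = mu
            mu_acc += mu
            kept += 1

    return pip / kept, bmean / kept, pvar / kept, trace[:kept], mu_acc / kept


def bslmm_sample(y_train, design: GenotypeDesign, cfg: BslmmConfig,
                 train_idx=None) -> PosteriorSummary:
    """Posterior summaries of the two-component sparse LMM on W genotypes."""
    y = np.asarray(y_train, dtype=float)
    tr = np.arange(design.n) if train_idx is None else np.asarray(train_idx, int)
    W = np.ascontiguousarray(design.W[tr], dtype=float)
    if y.size != W.shape[0]:
        raise ValueError("phenotype length must match training rows")
    m = W.shape[1]
    pi_b = float(cfg.pi_prior_b) if cfg.pi_prior_b is not None else m / 100.0
    pi_fixed = -1.0 if cfg.pi_fixed is None else float(cfg.pi_fixed)
    pip, bmean, pvar, trace, mu = _bslmm_chain(
        W, y, cfg.n_iter, cfg.burn_in, cfg.thin, cfg.pi_init, pi_fixed,
        1.0, pi_b, cfg.seed % (2**31 - 1))
    if not (np.isfinite(bmean).all() and np.isfinite(trace).all()):
        raise FloatingPointError("BSLMM chain diverged (non-finite state)")
    return PosteriorSummary(
        pip=pip, beta_mean=bmean, post_var=pvar, mu=float(mu), model="bslmm",
        trace={"pi": trace[:, 0], "v_small": trace[:, 1], "v_large": trace[:, 2],
               "sigma2_e": trace[:, 3], "mu": trace[:, 4]})


def bayesr_sample(y_train, design: GenotypeDesign, cfg: BayesrConfig,
                  train_idx=None) -> PosteriorSummary:
    """Posterior summaries of the four-class mixture model on W genotypes."""
    y = np.asarray(y_train, dtype=float)
    tr = np.arange(design.n) if train_idx is None else np.asarray(train_idx, int)
    W = np.ascontiguousarray(design.W[tr], dtype=float)
    if y.size != W.shape[0]:
        raise ValueError("phenotype length must match training rows")
    pip, bmean, pvar, trace, mu = _bayesr_chain(
        W, y, cfg.n_iter, cfg.burn_in, cfg.thin,
        np.asarray(cfg.dirichlet_alpha, dtype=float),
        np.asarray(BAYESR_CLASS_FRACTIONS, dtype=float), cfg.seed % (2**31 - 1))
    if not (np.isfinite(bmean).all() and np.isfinite(trace).all()):
        raise FloatingPointError("BayesR chain diverged (non-finite state)")
    return PosteriorSummary(
        pip=pip, beta_mean=bmean, post_var=pvar, mu=float(mu), model="bayesr",
        trace={"pi": trace[:, :4], "sigma2_g": trace[:, 4],
               "sigma2_e": trace[:, 5], "mu": trace[:, 6]})


def predict_from_posterior(summary: PosteriorSummary, design: GenotypeDesign,
                           train_idx, val_idx=None) -> Prediction:
    """Genomic values from posterior-mean SNP effects: ghat = W beta_bar."""
    tr = np.asarray(train_idx, dtype=int)
    va = (np.setdiff1d(np.arange(design.n), tr) if val_idx is None
          else np.asarray(val_idx, int))
    ghat = design.W @ summary.beta_mean
    return Prediction(samples=list(design.samples), ghat=ghat,
                      ghat_k=ghat[None, :], mu=summary.mu,
                      train_idx=tr, val_idx=va)
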