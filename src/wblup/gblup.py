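"""BLUP prediction from one or several GRMs, and SNP-effect back-solving.

Predictions use the GLS/mixed-model identity: with training-set variance
``V = sum_k sigma_k^2 G_k[train,train] + sigma_e^2 I`` and GLS intercept
``mu``, the genomic value of any individual (training or validation) is

    ghat_k = sigma_k^2 G_k[:, train] V^-1 (y_train - 1 mu)

summed over kernels. Validation individuals never enter ``V`` or ``mu``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .grm import BLEND_ALPHA, GenotypeDesign, Grm, WeightVector
from .varcomp import VarianceComponents

__all__ = ["Prediction", "SnpEffects", "gblup_predict", "backsolve_snp_effects"]


@dataclass
class Prediction:
    samples: list[str]
    ghat: np.ndarray            # per-sample total genomic value
    ghat_k: np.ndarray          # K x n per-kernel decomposition
    mu: float
    train_idx: np.ndarray
    val_idx: np.ndarray

    @property
    def ghat_train(self) -> np.ndarray:
        return self.ghat[self.train_idx]

    @property
    def ghat_val(self) -> np.ndarray:
        return self.ghat[self.val_idx]


@dataclass
class SnpEffects:
    beta: np.ndarray
    scale: str = "standardized"


def _kernel_values(k) -> np.ndarray:
    return k.values if isinstance(k, Grm) else np.asarray(k, dtype=float)


def gblup_predict(
    y_train: np.ndarray,
    kernels: list,
    vc: VarianceComponents,
    train_idx,
    val_idx=None,
    samples: list[str] | None = None,
) -> Prediction:
    """Multi-kernel GBLUP over train-plus-validation kernels.

    ``kernels`` are GRMs over the union of both sets; ``train_idx`` indexes
    the rows with phenotypes in ``y_train`` order.
    """
    y = np.asarray(y_train, dtype=float)
    tr = np.asarray(train_idx, dtype=int)
    mats = [_kernel_values(k) for k in kernels]
    n_all = mats[0].shape[0]
    if vc.sigma2.size != len(mats):
        raise ValueError("one genetic variance per kernel required")
    va = (np.setdiff1d(np.arange(n_all), tr) if val_idx is None
          else np.asarray(val_idx, dtype=int))

    V = np.zeros((tr.size, tr.size))
    for G, s2 in zip(mats, vc.sigma2):
        if s2 != 0.0:
            V += s2 * G[np.ix_(tr, tr)]
    V[np.diag_indices(tr.size)] += vc.sigma2_e
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    ones = np.ones(tr.size)
    Vi1 = linalg.cho_solve((c, low), ones, check_finite=False)
    mu = float(Vi1 @ y) / float(Vi1 @ ones)
    alpha = linalg.cho_solve((c, low), y - mu, check_finite=False)

    ghat_k = np.zeros((len(mats), n_all))
    for k, (G, s2) in enumerate(zip(mats, vc.sigma2)):
        if s2 != 0.0:
            ghat_k[k] = s2 * (G[:, tr] @ alpha)
    ghat = ghat_k.sum(axis=0)
    if samples is None:
        samples = [str(i) for i in range(n_all)]
    return Prediction(samples=samples, ghat=ghat, ghat_k=ghat_k, mu=mu,
                      train_idx=tr, val_idx=va)


def backsolve_snp_effects(
    p: Prediction,
    design: GenotypeDesign,
    w: WeightVector,
    blend: float = BLEND_ALPHA,
) -> SnpEffects:
    """SNP effects by linear transformation of genomic breeding values.

    Assumes the prediction came from the weighted GRM ``(1/m) W D W'``:
    ``beta = (1/m) D W_train' G_train^-1 ghat_train``. The training GRM is
    blended toward the identity before inversion.
    """
    tr = p.train_idx
    Wt = design.W[tr]
    m = design.m
    G = (Wt * w.d) @ Wt.T / m
    Gb = (1.0 - blend) * G + blend * np.eye(tr.size)
    sol = np.linalg.solve(Gb, p.ghat_train)
    beta = (w.d * (Wt.T @ sol)) / m
    return SnpEffects(beta=beta, scale="standardized")
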