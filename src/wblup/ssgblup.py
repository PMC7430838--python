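"""Desk-scale single-step GBLUP: pedigree A, combined H-inverse, and MME.

Single-step GBLUP merges pedigree relationships (numerator matrix A from
Henderson's tabular rules) with a genomic relationship matrix G over the
genotyped subset:

    H^-1 = A^-1 + [[0, 0], [0, G_adj^-1 - A22^-1]]

where A22 is the pedigree relationship block of the genotyped individuals
and G_adj is G tuned to A22 (two-coefficient adjustment matching the mean
diagonal and mean off-diagonal) and blended ``0.95 G + 0.05 A22`` — the
conventional defaults of the BLUPF90 family. Any weighted GRM can be
supplied, which is how the AM-BLUP / WPIP / IW weights enter single-step
evaluations.

EBVs come from the standard mixed-model equations with ``lambda =
sigma_e^2 / sigma_g^2``; everything is dense, intended for pedigrees up to a
few thousand animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .grm import Grm
from .io_formats import PedigreeTable, UNKNOWN_PARENT

__all__ = ["AMatrix", "SsModelSpec", "a_matrix", "h_inverse", "ssgblup_solve"]


@dataclass
class AMatrix:
    values: np.ndarray
    ids: list[str]              # topological (parents-first) order

    @property
    def index(self) -> dict:
        return {v: i for i, v in enumerate(self.ids)}


@dataclass
class SsModelSpec:
    sigma2_g: float
    sigma2_e: float
    tune_to_a22: bool = True
    blend_a22: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma2_g <= 0 or self.sigma2_e <= 0:
            raise ValueError("variances must be positive")


@njit(cache=True)
def _tabular(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    n = sire.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = a
            A[j, i] = a
    return A


def a_matrix(ped: PedigreeTable) -> AMatrix:
    """Numerator relationship matrix by Henderson's tabular method."""
    order = ped.topological_order()
    idx = {v: i for i, v in enumerate(order)}
    rec = ped.records.set_index("id")
    sire = np.empty(len(order), dtype=np.int64)
    dam = np.empty(len(order), dtype=np.int64)
    for i, ind in enumerate(order):
        s, d = rec.loc[ind, "sire"], rec.loc[ind, "dam"]
        sire[i] = idx[s] if s != UNKNOWN_PARENT else -1
        dam[i] = idx[d] if d != UNKNOWN_PARENT else -1
    return AMatrix(values=_tabular(sire, dam), ids=order)


def _adjust_g(G: np.ndarray, A22: np.ndarray, spec: SsModelSpec) -> np.ndarray:
    Gt = G
    if spec.tune_to_a22:
        off_g = (G.sum() - np.trace(G)) / (G.shape[0] ** 2 - G.shape[0])
        off_a = (A22.sum() - np.trace(A22)) / (A22.shape[0] ** 2 - A22.shape[0])
        denom = np.diag(G).mean() - off_g
        b = (np.diag(A22).mean() - off_a) / denom if denom != 0 else 1.0
        a = off_a - b * off_g
        Gt = a + b * G
    if spec.blend_a22 > 0:
        Gt = (1.0 - spec.blend_a22) * Gt + spec.blend_a22 * A22
    return Gt


def h_inverse(A: AMatrix, G: Grm, spec: SsModelSpec) -> np.ndarray:
    """H-inverse in the pedigree order of ``A``.

    ``G.samples`` must be a subset of the pedigree ids; with no genotyped
    individuals (or G identical to A22 with tuning/blending off) this reduces
    to A-inverse.
    """
    n = len(A.ids)
    idx = A.index
    Ainv = np.linalg.inv(A.values)
    if G is None or G.n == 0:
        return Ainv
    try:
        gpos = np.array([idx[s] for s in G.samples], dtype=int)
    except KeyError as e:
        raise ValueError(f"genotyped individual {e} not in pedigree") from e
    A22 = A.values[np.ix_(gpos, gpos)]
    Gadj = _adjust_g(G.values, A22, spec)
    Hinv = Ainv.copy()
    delta = np.linalg.inv(Gadj) - np.linalg.inv(A22)
    Hinv[np.ix_(gpos, gpos)] += delta
    return Hinv


def ssgblup_solve(
    y: np.ndarray,
    pheno_ids: list[str],
    ped: PedigreeTable,
    G: Grm | None,
    spec: SsModelSpec,
    X: np.ndarray | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """Solve the single-step mixed-model equations.

    Returns ``(EBVs indexed by pedigree id, fixed-effect estimates)``. ``X``
    is the fixed-effect design over the phenotype records (default:
    intercept). Accepts any (weighted) GRM over the genotyped subset.
    """
    y = np.asarray(y, dtype=float)
    A = a_matrix(ped)
    idx = A.index
    n_rec = y.size
    if len(pheno_ids) != n_rec:
        raise ValueError("one id per phenotype record required")
    X = np.ones((n_rec, 1)) if X is None else np.asarray(X, dtype=float)
    Z = np.zeros((n_rec, len(A.ids)))
    for r, ind in enumerate(pheno_ids):
        if ind not in idx:
            raise ValueError(f"phenotyped individual {ind} not in pedigree")
        Z[r, idx[ind]] = 1.0

    Hinv = h_inverse(A, G, spec)
    lam = spec.sigma2_e / spec.sigma2_g
    top = np.hstack([X.T @ X, X.T @ Z])
    bot = np.hstack([Z.T @ X, Z.T @ Z + lam * Hinv])
    lhs = np.vstack([top, bot])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    beta = sol[: X.shape[1]]
    u = sol[X.shape[1]:]
    return pd.Series(u, index=A.ids, name="ebv"), beta
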