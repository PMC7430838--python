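"""Single-SNP LMM score-test scan with Bonferroni threshold and peak calling.

Null variance components (intercept + one genome-wide GRM) are fitted once by
REML; each standardized SNP ``w_j`` is then tested with the score statistic

    T_j = U_j^2 / I_j,   U_j = w_j' P y,   I_j = w_j' P w_j,

where ``P`` projects out the intercept under the fitted null covariance
``V = sigma_g^2 G + sigma_e^2 I``; ``T_j ~ chi2_1`` under no association.
The tested SNP stays inside the GRM (no leave-one-chromosome-out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from .grm import GenotypeDesign, Grm
from .varcomp import reml_fit

__all__ = ["GwasResult", "Peak", "PeakSet", "score_scan", "bonferroni_threshold", "call_peaks"]


@dataclass
class GwasResult:
    table: pd.DataFrame         # snp, chrom, pos, freq, stat, p (genome order)
    h2_null: float


@dataclass
class Peak:
    lead_snp: str
    lead_p: float
    chrom: str
    start: int                  # bp span of the peak's significant SNPs
    end: int
    n_snps: int


@dataclass
class PeakSet:
    peaks: list


def score_scan(
    y_train,
    design: GenotypeDesign,
    background: Grm | np.ndarray,
    train_idx=None,
    max_iter: int = 100,
) -> GwasResult:
    y = np.asarray(y_train, dtype=float)
    tr = np.arange(design.n) if train_idx is None else np.asarray(train_idx, int)
    W = design.W[tr]
    G = background.values if isinstance(background, Grm) else np.asarray(background)
    G = G[np.ix_(tr, tr)] if G.shape[0] != tr.size else G

    null = reml_fit(y, [G], max_iter=max_iter)
    n = tr.size
    V = null.vc.sigma2[0] * G + null.vc.sigma2_e * np.eye(n)
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ones = np.ones(n)
    Vi1 = Vi @ ones
    P = Vi - np.outer(Vi1, Vi1) / float(ones @ Vi1)

    Py = P @ y
    U = W.T @ Py                      # score per SNP
    PW = P @ W
    I = np.einsum("ij,ij->j", W, PW)  # information per SNP
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(I > 0, U * U / I, 0.0)
    p = chi2.sf(stat, df=1)
    p = np.where(stat == 0.0, 1.0, p)

    snps = design.snps
    table = pd.DataFrame({
        "snp": design.snp_ids,
        "chrom": snps["chrom"].to_numpy() if snps is not None else "1",
        "pos": snps["pos"].to_numpy() if snps is not None else np.arange(design.m),
        "freq": design.freqs,
        "stat": stat,
        "p": p,
    })
    return GwasResult(table=table, h2_null=null.vc.h2)


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def call_peaks(res: GwasResult, threshold: float, merge_mb: float = 10.0) -> PeakSet:
    """Cluster significant SNPs in genome order; a new peak starts when the
    next significant SNP is more than ``merge_mb`` away or changes chromosome.
    The lead SNP is the smallest p (ties leftmost)."""
    merge_bp = merge_mb * 1e6
    sig = res.table[res.table["p"] < threshold]
    peaks: list[Peak] = []
    cur: list = []
    for row in sig.itertuples():
        if cur and (row.chrom != cur[-1].chrom or row.pos - cur[-1].pos > merge_bp):
            peaks.append(_make_peak(cur))
            cur = []
        cur.append(row)
    if cur:
        peaks.append(_make_peak(cur))
    return PeakSet(peaks=peaks)


def _make_peak(rows: list) -> Peak:
    best = min(rows, key=lambda r: (r.p, r.pos))
    return Peak(lead_snp=best.snp, lead_p=float(best.p), chrom=str(rows[0].chrom),
                start=int(rows[0].pos), end=int(rows[-1].pos), n_snps=len(rows))
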