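"""Genotype-matrix algebra and genomic relationship matrix (GRM) variants.

Notation: for individual ``i`` and SNP ``j`` with reference-allele dosage
``s_ij`` and reference allele frequency ``f_j``,

* centered dosage       ``x_ij = s_ij - 2 f_j``
* standardized dosage   ``w_ij = x_ij / sqrt(2 f_j (1 - f_j))``

GRM flavors built here:

* VanRaden               ``G  = X X' / sum_j 2 f_j (1 - f_j)``
* standardized           ``GS = (1/m) W W'``       (equal expected SNP variance)
* weighted standardized  ``Gw = (1/m) W D W'``     (D diagonal, trace m)
* chunk / region         standardized GRM on a SNP subset, divisor = subset size

Weight vectors live on the "trace contract": the diagonal of D sums to m, so
the mean SNP weight is 1 and the genetic-variance scale is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypeTable

__all__ = [
    "GenotypeDesign",
    "Grm",
    "WeightVector",
    "build_design",
    "vanraden_grm",
    "standardized_grm",
    "weighted_grm",
    "chunk_region_grm",
    "normalize_trace",
]

# GRMs are blended toward the identity before inversion-like uses; kept tiny
# so the blend perturbs predictions far less than sampling noise.
BLEND_ALPHA = 0.01


@dataclass
class GenotypeDesign:
    """Centered (X) and standardized (W) dosage matrices plus frequencies."""

    snp_ids: np.ndarray
    freqs: np.ndarray           # f_j, reference allele
    X: np.ndarray               # n x m centered dosages
    W: np.ndarray               # n x m standardized dosages
    samples: list[str]
    snps: object = None         # optional SNP map DataFrame (snp, chrom, pos)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class Grm:
    """Symmetric n x n relationship matrix with provenance."""

    values: np.ndarray
    samples: list[str]
    flavor: str = "vanraden"
    snp_indices: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def blended(self, alpha: float = BLEND_ALPHA) -> np.ndarray:
        """(1-alpha) G + alpha I, the matrix used wherever G is inverted."""
        return (1.0 - alpha) * self.values + alpha * np.eye(self.n)

    def submatrix(self, rows, cols=None) -> np.ndarray:
        rows = np.asarray(rows)
        cols = rows if cols is None else np.asarray(cols)
        return self.values[np.ix_(rows, cols)]


@dataclass
class WeightVector:
    """Per-SNP diagonal weights d_jj >= 0 with sum(d) = m."""

    d: np.ndarray
    provenance: str = "uniform"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if (self.d < 0).any():
            raise ValueError("weights must be non-negative")


def build_design(
    g: GenotypeTable,
    freqs: np.ndarray | None = None,
    min_freq: float = 0.005,
) -> GenotypeDesign:
    """Mean-impute missing calls and build X and W.

    ``freqs`` supplies external reference-allele frequencies; by default
    in-sample frequencies are used (then column means of X are 0).
    """
    calls = g.calls.astype(float)
    in_sample = g.allele_freq()
    if np.isnan(in_sample).any():
        bad = g.snps.loc[np.isnan(in_sample), "snp"].iloc[0]
        raise ValueError(f"SNP {bad} has no observed calls")
    f = in_sample if freqs is None else np.asarray(freqs, dtype=float)
    out = (f <= min_freq) | (f >= 1 - min_freq)
    if out.any():
        bad = g.snps.loc[out, "snp"].iloc[0]
        raise ValueError(
            f"SNP {bad} has frequency outside ({min_freq}, {1 - min_freq}); "
            "monomorphic or near-monomorphic SNPs cannot be standardized")
    # mean imputation at 2 f_j (per-SNP expected dosage)
    miss = g.calls == MISSING
    if miss.any():
        fill = np.broadcast_to(2.0 * in_sample, calls.shape)
        calls = np.where(miss, fill, calls)
    X = calls - 2.0 * f
    W = X / np.sqrt(2.0 * f * (1.0 - f))
    return GenotypeDesign(snp_ids=g.snps["snp"].to_numpy(), freqs=f, X=X, W=W,
                          samples=list(g.samples), snps=g.snps)


def vanraden_grm(d: GenotypeDesign) -> Grm:
    """G = X X' / sum_j 2 f_j (1 - f_j)."""
    denom = float(np.sum(2.0 * d.freqs * (1.0 - d.freqs)))
    if denom <= 0:
        raise ValueError("zero denominator in VanRaden GRM")
    return Grm(values=(d.X @ d.X.T) / denom, samples=d.samples, flavor="vanraden")


def standardized_grm(d: GenotypeDesign) -> Grm:
    """GS = (1/m) W W'."""
    return Grm(values=(d.W @ d.W.T) / d.m, samples=d.samples, flavor="standardized")


def weighted_grm(d: GenotypeDesign, w: WeightVector) -> Grm:
    """Gw = (1/m) W D W' with trace-m weights (mean weight 1)."""
    if w.d.shape[0] != d.m:
        raise ValueError("weight vector length must equal SNP count")
    vals = (d.W * w.d) @ d.W.T / d.m
    return Grm(values=vals, samples=d.samples, flavor="weighted")


def chunk_region_grm(d: GenotypeDesign, snp_subset) -> Grm:
    """Standardized GRM restricted to a SNP subset; divisor = subset size."""
    idx = np.asarray(snp_subset, dtype=int)
    if idx.size == 0:
        raise ValueError("empty SNP subset")
    Wk = d.W[:, idx]
    return Grm(values=(Wk @ Wk.T) / idx.size, samples=d.samples,
               flavor="chunk", snp_indices=idx)


def normalize_trace(raw: np.ndarray, provenance: str = "uniform",
                    m: int | None = None) -> WeightVector:
    """Rescale non-negative raw per-SNP variances so their sum equals m."""
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("raw weights must be non-negative")
    total = raw.sum()
    if total == 0:
        raise ValueError("all-zero weight vector")
    m = raw.size if m is None else m
    return WeightVector(d=(raw / total) * m, provenance=provenance)


def am_weight_vector(groups, sigma2, m: int,
                     provenance: str = "amblup") -> WeightVector:
    """Per-SNP weights from per-group variances: d = (s2_k/m_k) / (s2_T/m).

    ``groups`` are SNP index sets partitioning (a subset of) the panel and
    ``sigma2`` their estimated variances; SNPs outside every group keep
    weight 1 only if the groups do not cover the panel and total variance is
    zero — in the usual case groups partition the panel and the trace is m
    by construction. Division by the mean per-SNP variance s2_T/m keeps
    tr(D) = m.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    sigma_T = float(sigma2.sum())
    d = np.ones(m)
    if sigma_T > 0:
        per_snp = sigma_T / m
        for idx, s2 in zip(groups, sigma2):
            idx = np.asarray(idx, dtype=int)
            d[idx] = (s2 / idx.size) / per_snp
    return normalize_trace(d, provenance=provenance, m=m)
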