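"""Adaptive MultiBLUP genome scan and its permutation/bootstrap refinement.

Pipeline:

1. ``make_chunks`` tiles each chromosome with fixed-bp windows (default 1 Mb,
   50% overlap between successive chunks).
2. ``chunk_scan`` tests each chunk with a boundary LRT: background kernel =
   standardized GRM on all SNPs outside the chunk, region kernel = chunk GRM.
3. ``form_regions`` seeds regions at chunks with p < thr1 (default 1e-5) and
   grows them over contiguous chunks with p < thr2 (default 0.01).
4. ``amblup_fit`` estimates the K+1 variance components jointly and converts
   them into per-SNP weights d_i = (sigma_k^2 / m_k) / (sigma_T^2 / m), whose
   trace is m by construction.
5. ``permutation_threshold`` and ``bootstrap_ci`` implement the refined
   variant (BAM-BLUP): an empirical genome-wide threshold from the best
   chunk p-value under phenotype permutation, and per-region bootstrap
   confidence sets of chunks.

Tie-breaks are always leftmost (smallest chromosome label in panel order,
then bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grm import GenotypeDesign, Grm, WeightVector, am_weight_vector, normalize_trace
from .varcomp import RemlFit, lrt_region, reml_fit

__all__ = [
    "ScanConfig",
    "Chunk",
    "ChunkScan",
    "Region",
    "RegionSet",
    "PermutationNull",
    "BootstrapCI",
    "make_chunks",
    "chunk_scan",
    "form_regions",
    "merge_close_regions",
    "amblup_fit",
    "permutation_threshold",
    "select_ci_windows",
    "bootstrap_ci",
    "bam_blup_regions",
]


@dataclass
class ScanConfig:
    chunk_size: int = 1_000_000
    overlap: float = 0.5
    thr1: float = 1e-5
    thr2: float = 0.01
    merge_gap: int = 10_000_000
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    df_convention: str = "mixture"

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap < 1.0:
            raise ValueError("overlap must be in (0,1)")
        if not self.thr1 < self.thr2:
            raise ValueError("thr1 must be below thr2")

    @property
    def step(self) -> int:
        return int(round(self.chunk_size * (1.0 - self.overlap)))


@dataclass
class Chunk:
    chrom: str
    start: int
    end: int                    # half-open [start, end)
    snp_idx: np.ndarray         # global SNP indices


@dataclass
class ChunkScan:
    chunks: list
    pvalues: np.ndarray         # NaN where the REML fit failed
    statistics: np.ndarray

    def min_index(self) -> int:
        """Index of the smallest p-value; ties go to the leftmost chunk."""
        p = np.where(np.isnan(self.pvalues), np.inf, self.pvalues)
        return int(np.argmin(p))


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    snp_idx: np.ndarray
    chunks: list = field(default_factory=list)

    @property
    def m_k(self) -> int:
        return int(self.snp_idx.size)


@dataclass
class RegionSet:
    regions: list
    background_idx: np.ndarray
    m: int

    def validate(self) -> None:
        parts = [r.snp_idx for r in self.regions] + [self.background_idx]
        allidx = np.concatenate(parts) if parts else np.array([], int)
        if allidx.size != self.m or np.unique(allidx).size != self.m:
            raise AssertionError("regions + background must partition the SNP panel")

    @property
    def K(self) -> int:
        return len(self.regions)


@dataclass
class PermutationNull:
    min_pvalues: np.ndarray
    threshold: float
    quantile: float


@dataclass
class BootstrapCI:
    flag_counts: np.ndarray     # per candidate window, sums to n_bootstrap
    selected: np.ndarray        # indices into the region's chunk list
    windows: list               # the candidate Chunk objects
    span: tuple                 # (chrom, start, end) over selected windows
    snp_idx: np.ndarray         # union of selected windows' SNPs
    contiguous: bool
    n_bootstrap: int


# ---------------------------------------------------------------------------
# chunking and scanning
# ---------------------------------------------------------------------------

class _ChunkScanEngine:
    """Fast exact-REML chunk LRTs via one eigendecomposition per dataset.

    With GS = U L U' the full standardized GRM, the scan covariance for a
    chunk c is, after profiling out the residual variance sigma_e^2 and
    rotating by U,

        M = I + g0 * (m L - C C') / (m - mc) + gc * C C' / mc,
            C = U' W_c,  g_k = sigma_k^2 / sigma_e^2,

    i.e. diagonal plus a rank-mc update, so every restricted-likelihood
    evaluation costs O(n mc^2) instead of O(n^3). The null (background-only)
    and full (background + chunk) models are maximized over the variance
    ratios on the log scale; the optimum is the same REML optimum the dense
    path finds, which the test suite cross-checks.
    """

    def __init__(self, y, W, background=None):
        """Scan mode (background = panel minus chunk) when ``background`` is
        None; otherwise the supplied matrix is the fixed background kernel and
        chunks are independent low-rank additions (bootstrap use)."""
        self.n, self.m = W.shape
        G = (W @ W.T) / self.m if background is None else np.asarray(background)
        lam, U = np.linalg.eigh(G)
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        self.W = W
        self.fixed_bg = background is not None
        self.ot = U.T @ np.ones(self.n)
        self.set_phenotype(y)

    def set_phenotype(self, y) -> None:
        self.yt = self.U.T @ np.asarray(y, dtype=float)

    def _loglik(self, g0, gc, C, mc):
        n, m = self.n, self.m
        if self.fixed_bg:
            d = 1.0 + g0 * self.lam
            beta = gc / mc
        else:
            d = 1.0 + g0 * (m / (m - mc)) * self.lam
            beta = gc / mc - g0 / (m - mc)
        yd = self.yt / d
        od = self.ot / d
        s_yy = float(self.yt @ yd)
        s_oo = float(self.ot @ od)
        s_oy = float(self.ot @ yd)
        logdet = float(np.sum(np.log(d)))
        if beta != 0.0:
            Z = C / d[:, None]
            T = C.T @ Z
            B = np.eye(mc) + beta * T
            sign, ld_b = np.linalg.slogdet(B)
            if sign <= 0:
                return -np.inf
            logdet += ld_b
            a = Z.T @ self.yt
            b = Z.T @ self.ot
            try:
                Bia = np.linalg.solve(B, np.column_stack([a, b]))
            except np.linalg.LinAlgError:
                return -np.inf
            s_yy -= beta * float(a @ Bia[:, 0])
            s_oo -= beta * float(b @ Bia[:, 1])
            s_oy -= beta * float(b @ Bia[:, 0])
        if s_oo <= 0:
            return -np.inf
        ypy = s_yy - s_oy ** 2 / s_oo
        if ypy <= 0:
            return -np.inf
        nm = n - 1
        sig_e = ypy / nm
        return -0.5 * (nm * (np.log(sig_e) + 1.0 + np.log(2.0 * np.pi))
                       + logdet + np.log(s_oo))

    def null_fit(self, C, mc):
        """Maximize over the background ratio g0 >= 0 (gc = 0)."""
        from scipy.optimize import minimize_scalar

        def neg(t):
            return -self._loglik(np.exp(t), 0.0, C, mc)

        res = minimize_scalar(neg, bounds=(-16.0, 8.0), method="bounded",
                              options={"xatol": 1e-6})
        best_t, best = res.x, -res.fun
        at_zero = self._loglik(0.0, 0.0, C, mc)
        if at_zero >= best:
            return 0.0, at_zero
        return float(np.exp(best_t)), best

    def chunk_lrt(self, snp_idx, df_convention="mixture"):
        C = self.U.T @ self.W[:, snp_idx]
        return self._prepared_lrt(C, len(snp_idx), df_convention)

    def scan(self, chunk_cs, df_convention="mixture"):
        """LRT over prepared chunks: list of (C, snp_count) pairs."""
        stats = np.full(len(chunk_cs), np.nan)
        pvals = np.full(len(chunk_cs), np.nan)
        for i, (C, mc) in enumerate(chunk_cs):
            try:
                stats[i], pvals[i] = self._prepared_lrt(C, mc, df_convention)
            except (ValueError, np.linalg.LinAlgError):
                continue
        return stats, pvals

    def prepare(self, chunks):
        return [(self.U.T @ self.W[:, ch.snp_idx], ch.snp_idx.size)
                for ch in chunks]

    def _prepared_lrt(self, C, mc, df_convention):
        from scipy.stats import chi2
        if mc >= self.m:
            raise ValueError("chunk covers the whole panel; no background left")
        stat = self._lrt_from_c(C, mc)
        if stat == 0.0:
            p = 1.0
        elif df_convention == "mixture":
            p = 0.5 * float(chi2.sf(stat, df=1))
        else:
            p = float(chi2.sf(stat, df=1))
        return stat, p

    def _lrt_from_c(self, C, mc):
        from scipy.optimize import minimize, minimize_scalar

        g0_null, ll_null = self.null_fit(C, mc)

        def neg(t):
            return -self._loglik(np.exp(t[0]), np.exp(t[1]), C, mc)

        t0 = np.log(max(g0_null, 1e-8))
        grid = [-8.0, -5.0, -3.0, -1.5, 0.0, 1.5]
        seed_tc = min(grid, key=lambda tc: neg([t0, tc]))
        res = minimize(neg, x0=[t0, seed_tc], method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 400})
        ll_full = max(-res.fun, ll_null)

        def neg_c(tc):
            return -self._loglik(0.0, np.exp(tc), C, mc)
        res0 = minimize_scalar(neg_c, bounds=(-16.0, 8.0), method="bounded",
                               options={"xatol": 1e-6})
        ll_full = max(ll_full, -res0.fun)
        return max(2.0 * (ll_full - ll_null), 0.0)

def make_chunks(snps, cfg: ScanConfig) -> list:
    """Half-open fixed-size windows on the chunk grid; empty chunks dropped.

    ``snps`` is the SNP map DataFrame (columns chrom, pos) sorted by
    (chromosome, bp).
    """
    chunks: list[Chunk] = []
    pos_all = snps["pos"].to_numpy()
    chrom_all = snps["chrom"].to_numpy()
    step = cfg.step
    for chrom in dict.fromkeys(chrom_all):  # preserves panel order
        on_c = np.flatnonzero(chrom_all == chrom)
        pos = pos_all[on_c]
        first, last = int(pos.min()), int(pos.max())
        start = (first // step) * step
        while start <= last:
            end = start + cfg.chunk_size
            inside = on_c[(pos >= start) & (pos < end)]
            if inside.size:
                chunks.append(Chunk(chrom=str(chrom), start=start, end=end,
                                    snp_idx=inside))
            start += step
    return chunks


def chunk_scan(
    y_train,
    design: GenotypeDesign,
    cfg: ScanConfig,
    train_idx=None,
    chunks: list | None = None,
    engine: _ChunkScanEngine | None = None,
) -> ChunkScan:
    """Per-chunk boundary LRT against an all-other-SNPs background kernel.

    Runs on the eigendecomposition engine (one O(n^3) factorization per
    dataset, O(n mc^2) per likelihood evaluation). Chunks whose fit fails get
    a NaN p-value and the scan continues. A chunk covering the entire panel
    is tested against a residual-only null.
    """
    y = np.asarray(y_train, dtype=float)
    tr = np.arange(design.n) if train_idx is None else np.asarray(train_idx, int)
    W = design.W[tr]
    if y.size != tr.size:
        raise ValueError("phenotype length must match the training index")
    m = design.m
    if chunks is None:
        if design.snps is None:
            raise ValueError("design lacks a SNP map; pass chunks explicitly")
        chunks = make_chunks(design.snps, cfg)

    if engine is None:
        engine = _ChunkScanEngine(y, W)
    else:
        engine.set_phenotype(y)

    pvals = np.full(len(chunks), np.nan)
    stats = np.full(len(chunks), np.nan)
    for i, ch in enumerate(chunks):
        mc = ch.snp_idx.size
        if mc >= m:  # degenerate one-chunk genome: residual-only null
            Wc = W[:, ch.snp_idx]
            try:
                res = lrt_region(y, None, (Wc @ Wc.T) / mc,
                                 df_convention=cfg.df_convention)
            except (ValueError, np.linalg.LinAlgError):
                continue
            stats[i], pvals[i] = res.statistic, res.pvalue
            continue
        try:
            stats[i], pvals[i] = engine.chunk_lrt(ch.snp_idx, cfg.df_convention)
        except (ValueError, np.linalg.LinAlgError):
            continue
    return ChunkScan(chunks=chunks, pvalues=pvals, statistics=stats)


def form_regions(scan: ChunkScan, cfg: ScanConfig, m: int) -> RegionSet:
    """Grow thr2-regions around thr1-significant seed chunks.

    Seeds extend over contiguous same-chromosome chunks with p < thr2;
    grown regions sharing chunks or touching coalesce. Remaining SNPs form
    the background.
    """
    p = scan.pvalues
    chunks = scan.chunks
    n_ch = len(chunks)
    selected = np.zeros(n_ch, dtype=bool)
    seeds = [i for i in range(n_ch) if not np.isnan(p[i]) and p[i] < cfg.thr1]
    for s in seeds:
        selected[s] = True
        j = s - 1
        while j >= 0 and chunks[j].chrom == chunks[s].chrom and not np.isnan(p[j]) and p[j] < cfg.thr2:
            selected[j] = True
            j -= 1
        j = s + 1
        while j < n_ch and chunks[j].chrom == chunks[s].chrom and not np.isnan(p[j]) and p[j] < cfg.thr2:
            selected[j] = True
            j += 1

    regions: list[Region] = []
    i = 0
    while i < n_ch:
        if not selected[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n_ch and selected[j + 1]
               and chunks[j + 1].chrom == chunks[i].chrom):
            j += 1
        members = chunks[i: j + 1]
        snp_idx = np.unique(np.concatenate([c.snp_idx for c in members]))
        regions.append(Region(chrom=members[0].chrom, start=members[0].start,
                              end=members[-1].end, snp_idx=snp_idx,
                              chunks=list(members)))
        i = j + 1

    # coalesce regions that share SNPs (possible through chunk overlap)
    merged: list[Region] = []
    for r in regions:
        if merged and merged[-1].chrom == r.chrom and np.intersect1d(
                merged[-1].snp_idx, r.snp_idx).size:
            prev = merged.pop()
            merged.append(Region(
                chrom=r.chrom, start=prev.start, end=max(prev.end, r.end),
                snp_idx=np.unique(np.r_[prev.snp_idx, r.snp_idx]),
                chunks=prev.chunks + r.chunks))
        else:
            merged.append(r)

    in_region = (np.unique(np.concatenate([r.snp_idx for r in merged]))
                 if merged else np.array([], int))
    background = np.setdiff1d(np.arange(m), in_region)
    rs = RegionSet(regions=merged, background_idx=background, m=m)
    rs.validate()
    return rs


def merge_close_regions(rs: RegionSet, gap_bp: int) -> RegionSet:
    """Merge same-chromosome regions whose bp spans are less than gap_bp apart."""
    merged: list[Region] = []
    for r in rs.regions:
        if (merged and merged[-1].chrom == r.chrom
                and r.start - merged[-1].end < gap_bp):
            prev = merged.pop()
            merged.append(Region(
                chrom=r.chrom, start=prev.start, end=max(prev.end, r.end),
                snp_idx=np.unique(np.r_[prev.snp_idx, r.snp_idx]),
                chunks=prev.chunks + r.chunks))
        else:
            merged.append(r)
    out = RegionSet(regions=merged, background_idx=rs.background_idx, m=rs.m)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# multi-kernel fit and weights
# ---------------------------------------------------------------------------

def amblup_fit(
    y_train,
    design: GenotypeDesign,
    regions: RegionSet,
    train_idx=None,
    max_iter: int = 100,
) -> tuple[RemlFit, WeightVector]:
    """K+1-kernel REML over (background, region_1..region_K) and AM weights.

    With no regions this degenerates to the standardized GBLUP fit and
    uniform weights.
    """
    y = np.asarray(y_train, dtype=float)
    tr = np.arange(design.n) if train_idx is None else np.asarray(train_idx, int)
    W = design.W[tr]
    m = design.m

    groups = [regions.background_idx] + [r.snp_idx for r in regions.regions]
    if regions.background_idx.size == 0:
        groups = groups[1:]
    kernels = []
    for idx in groups:
        Wk = W[:, idx]
        kernels.append(Wk @ Wk.T / idx.size)
    fit = reml_fit(y, kernels, max_iter=max_iter)

    weights = am_weight_vector(groups, fit.vc.sigma2, m, provenance="amblup")
    weights.meta["sigma2"] = fit.vc.sigma2.tolist()
    weights.meta["groups"] = [int(g.size) for g in groups]
    return fit, weights


# ---------------------------------------------------------------------------
# permutations and bootstraps
# ---------------------------------------------------------------------------

def permutation_threshold(
    y_train,
    design: GenotypeDesign,
    cfg: ScanConfig,
    train_idx=None,
    quantile: float = 0.05,
) -> PermutationNull:
    """Empirical genome-wide threshold from permuted-phenotype scans.

    Phenotypes are permuted (genotypes untouched); the scan's minimum chunk
    p-value is recorded per permutation and the configured quantile of those
    minima (linear type-7 interpolation) is the threshold.
    """
    rng = np.random.default_rng(cfg.seed)
    y = np.asarray(y_train, dtype=float)
    tr = np.arange(design.n) if train_idx is None else np.asarray(train_idx, int)
    chunks = make_chunks(design.snps, cfg)
    engine = _ChunkScanEngine(y, design.W[tr])
    prepared = engine.prepare(chunks)
    minima = np.empty(cfg.n_permutations)
    for b in range(cfg.n_permutations):
        engine.set_phenotype(rng.permutation(y))
        _, pvals = engine.scan(prepared, df_convention=cfg.df_convention)
        p = pvals[~np.isnan(pvals)]
        minima[b] = p.min() if p.size else 1.0
    thr = float(np.quantile(minima, quantile))
    return PermutationNull(min_pvalues=minima, threshold=thr, quantile=quantile)


def select_ci_windows(counts, need: float) -> np.ndarray:
    """Smallest set of windows whose flag counts reach ``need``.

    Greedy by descending count (optimal for this objective); ties go to the
    leftmost window. Returns sorted window indices.
    """
    counts = np.asarray(counts)
    order = sorted(range(counts.size), key=lambda j: (-counts[j], j))
    cum = 0
    chosen: list[int] = []
    for j in order:
        chosen.append(j)
        cum += counts[j]
        if cum >= need:
            break
    return np.sort(np.array(chosen, dtype=int))


def bootstrap_ci(
    y_train,
    design: GenotypeDesign,
    region: Region,
    cfg: ScanConfig,
    train_idx=None,
) -> BootstrapCI:
    """Bootstrap confidence set of windows within a significant region.

    Individuals are resampled with replacement; per sample, the region chunk
    with the lowest LRT p-value (background = SNPs outside the region, shared
    across the region's windows within a sample) is flagged, ties going
    leftmost. The CI is the smallest set of windows, taken by descending flag
    count, whose counts reach ci_level of the bootstrap draws.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    y = np.asarray(y_train, dtype=float)
    tr = np.arange(design.n) if train_idx is None else np.asarray(train_idx, int)
    W = design.W[tr]
    n = tr.size
    windows = list(region.chunks)
    if not windows:
        raise ValueError("region has no candidate windows")

    bg_idx = np.setdiff1d(np.arange(design.m), region.snp_idx)
    Wb = W[:, bg_idx]
    G_bg = Wb @ Wb.T / bg_idx.size

    counts = np.zeros(len(windows), dtype=int)
    for b in range(cfg.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        # one background eigendecomposition per bootstrap sample; each
        # window's LRT is then a cheap low-rank update, and the best window
        # is the largest statistic (p is monotone in it)
        try:
            eng = _ChunkScanEngine(yb, W[idx], background=G_bg[np.ix_(idx, idx)])
        except np.linalg.LinAlgError:
            continue
        best_j, best_stat = 0, -np.inf
        for j, ch in enumerate(windows):
            C = eng.U.T @ W[np.ix_(idx, ch.snp_idx)]
            try:
                stat = eng._lrt_from_c(C, ch.snp_idx.size)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if stat > best_stat:
                best_stat, best_j = stat, j
        counts[best_j] += 1

    chosen_arr = select_ci_windows(counts, cfg.ci_level * cfg.n_bootstrap)
    sel_windows = [windows[j] for j in chosen_arr]
    snp_idx = np.unique(np.concatenate([c.snp_idx for c in sel_windows]))
    contiguous = bool(np.all(np.diff(chosen_arr) == 1))
    span = (region.chrom, min(c.start for c in sel_windows),
            max(c.end for c in sel_windows))
    return BootstrapCI(flag_counts=counts, selected=chosen_arr, windows=windows,
                       span=span, snp_idx=snp_idx, contiguous=contiguous,
                       n_bootstrap=cfg.n_bootstrap)


def bam_blup_regions(
    y_train,
    design: GenotypeDesign,
    cfg: ScanConfig,
    train_idx=None,
    scan: ChunkScan | None = None,
    perm: PermutationNull | None = None,
) -> tuple[RegionSet, dict]:
    """Permutation/bootstrap-refined region set (BAM-BLUP).

    The scan's thr1 is replaced by the permutation threshold; regions less
    than merge_gap apart are merged; each region is reduced to its bootstrap
    confidence set of windows.
    """
    if scan is None:
        scan = chunk_scan(y_train, design, cfg, train_idx=train_idx)
    if perm is None:
        perm = permutation_threshold(y_train, design, cfg, train_idx=train_idx)
    from dataclasses import replace
    cfg_emp = replace(cfg, thr1=max(perm.threshold, np.nextafter(0, 1)),
                      thr2=max(cfg.thr2, perm.threshold))
    rs = form_regions(scan, cfg_emp, m=design.m)
    rs = merge_close_regions(rs, cfg.merge_gap)
    refined: list[Region] = []
    cis = []
    for r in rs.regions:
        ci = bootstrap_ci(y_train, design, r, cfg, train_idx=train_idx)
        cis.append(ci)
        refined.append(Region(chrom=ci.span[0], start=ci.span[1], end=ci.span[2],
                              snp_idx=ci.snp_idx, chunks=[ci.windows[j] for j in ci.selected]))
    in_region = (np.unique(np.concatenate([r.snp_idx for r in refined]))
                 if refined else np.array([], int))
    out = RegionSet(regions=refined,
                    background_idx=np.setdiff1d(np.arange(design.m), in_region),
                    m=design.m)
    out.validate()
    return out, {"scan": scan, "permutation": perm, "bootstrap": cis}
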