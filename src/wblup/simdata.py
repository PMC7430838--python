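"""Cattle-like genotype, pedigree and trait-deviation simulator.

The generator produces a truth-known substrate for every prediction method in
the package: a multi-generation pedigree, SNP genotypes with LD along each
chromosome, and trait deviations controlled by a QTL architecture (a handful
of large-effect regions plus a polygenic background).

Genotypes: founder haplotypes follow a first-order Markov chain along each
chromosome, with neighbor-allele correlation decaying exponentially with bp
distance; descendants receive gametes by gene-drop with Haldane recombination.
This creates multi-SNP blocks that tag QTLs the way a medium-density cattle
panel does, without modelling demography.

Traits: effects are drawn on the standardized-genotype scale and rescaled
in-sample so each region's share of the genetic variance and the trait
heritability are hit exactly, which keeps parameter-recovery tests sharp.
The train/validation split withholds the most recent generation (15% of
individuals by default, mimicking a date-based cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable, PedigreeTable, PhenotypeTable, UNKNOWN_PARENT

__all__ = [
    "TraitSpec",
    "SimConfig",
    "TrueGenetics",
    "DatasetBundle",
    "simulate_genotypes",
    "simulate_trait",
    "make_dataset",
]


@dataclass
class TraitSpec:
    """Architecture of one simulated trait deviation.

    ``region_fractions`` are shares of the *genetic* variance carried by each
    large-effect region; the remainder is polygenic background.
    """

    name: str
    h2: float = 0.4
    region_fractions: tuple = ()
    snps_per_region: int = 1
    region_width_bp: int = 1_000_000
    qtl_freq_range: tuple | None = None   # e.g. (0.01, 0.14) for coding-like variants

    def __post_init__(self) -> None:
        fr = np.asarray(self.region_fractions, dtype=float)
        if ((fr < 0) | (fr > 1)).any() or fr.sum() >= 1.0:
            raise ValueError("region variance fractions must lie in [0,1) and sum below 1")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0,1]")


def default_traits() -> list[TraitSpec]:
    """Three architectures typical of beef-cattle conformation traits:
    many-region muscling-like, two large regions (skin-thickness-like),
    and purely polygenic."""
    return [
        TraitSpec(name="muscling", h2=0.4, region_fractions=(0.05, 0.04, 0.03, 0.03, 0.03)),
        TraitSpec(name="skin_thickness", h2=0.4, region_fractions=(0.065, 0.065)),
        TraitSpec(name="polygenic", h2=0.4, region_fractions=()),
    ]


@dataclass
class SimConfig:
    seed: int = 2020
    n_individuals: int = 1000
    n_chromosomes: int = 5
    chrom_length_bp: int = 25_000_000   # 16 SNPs/Mb, like a medium-density array
    snps_per_chrom: int = 400
    maf_range: tuple = (0.05, 0.5)
    ld_r0: float = 0.95             # neighbor correlation at zero distance
    ld_decay_bp: float = 100_000.0  # e-folding distance of neighbor correlation
    recomb_rate: float = 1e-8       # Morgans per bp (1 cM/Mb)
    generation_fractions: tuple = (0.25, 0.30, 0.30, 0.15)  # last = validation
    ungenotyped_fraction: float = 0.0  # of non-validation individuals (ssGBLUP)
    traits: list = field(default_factory=default_traits)

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.snps_per_chrom <= 0 or self.n_chromosomes <= 0:
            raise ValueError("individuals, chromosomes and SNP counts must be positive")
        fr = np.asarray(self.generation_fractions, dtype=float)
        if not (fr > 0).all() or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("generation fractions must be positive and sum to 1")
        if not 0.0 < fr[-1] < 1.0:
            raise ValueError("validation (last-generation) fraction must be in (0,1)")


@dataclass
class TrueGenetics:
    g_true: pd.Series               # per-individual true breeding value
    beta: np.ndarray                # per-SNP effect on the standardized scale
    regions: list                   # dicts: chrom, start, end, snp_indices, fraction
    sigma2_g: float
    sigma2_e: float
    h2: float


@dataclass
class DatasetBundle:
    genotypes: GenotypeTable        # genotyped individuals only
    phenotypes: PhenotypeTable      # all phenotyped individuals
    pedigree: PedigreeTable
    truth: dict                     # trait name -> TrueGenetics
    train_ids: list
    val_ids: list
    generation: pd.Series           # id -> generation index
    config: SimConfig


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _markov_haplotypes(rng, freqs, pos, n_hap, r0, d0):
    """First-order Markov haplotypes: corr(h_j, h_{j+1}) = r0 exp(-d/d0),
    clipped to the Frechet-feasible range for the marginal frequencies."""
    m = freqs.size
    H = np.empty((n_hap, m), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, m):
        f1, f2 = freqs[j - 1], freqs[j]
        r = r0 * np.exp(-(pos[j] - pos[j - 1]) / d0)
        p11 = f1 * f2 + r * np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
        p11 = min(max(p11, max(0.0, f1 + f2 - 1.0)), min(f1, f2))
        p_given1 = p11 / f1
        p_given0 = (f2 - p11) / (1.0 - f1)
        prev = H[:, j - 1] == 1
        u = rng.random(n_hap)
        H[:, j] = np.where(prev, u < p_given1, u < p_given0)
    return H


def _meiosis(rng, hap_a, hap_b, pos, recomb_rate):
    """One gamete from a parent's two chromosome haplotypes (Haldane map)."""
    m = pos.size
    d = np.diff(pos) * recomb_rate  # Morgans between adjacent SNPs
    c = 0.5 * (1.0 - np.exp(-2.0 * d))
    cross = rng.random(m - 1) < c
    phase = np.empty(m, dtype=bool)
    phase[0] = rng.random() < 0.5
    phase[1:] = np.logical_xor.accumulate(cross) ^ phase[0]
    return np.where(phase, hap_a, hap_b)


def _generation_sizes(cfg: SimConfig) -> np.ndarray:
    fr = np.asarray(cfg.generation_fractions, dtype=float)
    sizes = np.maximum(np.round(fr * cfg.n_individuals).astype(int), 2)
    sizes[-1] += cfg.n_individuals - sizes.sum()
    return sizes


def simulate_genotypes(cfg: SimConfig):
    """Simulate genotypes for every pedigree member.

    Returns ``(GenotypeTable, PedigreeTable, generation Series)`` over all
    individuals; reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0)))
    lo, hi = cfg.maf_range
    sizes = _generation_sizes(cfg)
    n_total = int(sizes.sum())
    ids = [f"I{i + 1:05d}" for i in range(n_total)]
    gen_of = np.repeat(np.arange(sizes.size), sizes)

    # SNP map
    chroms, positions, freqs = [], [], []
    for c in range(cfg.n_chromosomes):
        pos = np.sort(rng.choice(
            np.arange(1, cfg.chrom_length_bp + 1), size=cfg.snps_per_chrom,
            replace=False))
        maf = rng.uniform(lo, hi, size=cfg.snps_per_chrom)
        flip = rng.random(cfg.snps_per_chrom) < 0.5
        f = np.where(flip, 1.0 - maf, maf)  # reference allele can be major or minor
        chroms.append(np.full(cfg.snps_per_chrom, str(c + 1), dtype=object))
        positions.append(pos)
        freqs.append(f)
    snps = pd.DataFrame({
        "snp": [f"snp{c + 1}_{k + 1}" for c in range(cfg.n_chromosomes)
                for k in range(cfg.snps_per_chrom)],
        "chrom": np.concatenate(chroms),
        "pos": np.concatenate(positions).astype(int),
        "allele": "A",
    })

    # haplotypes per chromosome: founders by Markov chain, descendants by gene-drop
    n_founders = int(sizes[0])
    hapA = []  # per chromosome: (n_total, m_c) int8
    hapB = []
    sire_idx = np.full(n_total, -1)
    dam_idx = np.full(n_total, -1)
    start = n_founders
    prev_lo, prev_hi = 0, n_founders
    for gsize in sizes[1:]:
        for i in range(start, start + int(gsize)):
            s, d = rng.choice(np.arange(prev_lo, prev_hi), size=2, replace=False)
            sire_idx[i], dam_idx[i] = s, d
        prev_lo, prev_hi = start, start + int(gsize)
        start += int(gsize)

    for c in range(cfg.n_chromosomes):
        pos = positions[c]
        f = freqs[c]
        A = np.empty((n_total, pos.size), dtype=np.int8)
        B = np.empty((n_total, pos.size), dtype=np.int8)
        A[:n_founders] = _markov_haplotypes(rng, f, pos, n_founders, cfg.ld_r0,
                                            cfg.ld_decay_bp)
        B[:n_founders] = _markov_haplotypes(rng, f, pos, n_founders, cfg.ld_r0,
                                            cfg.ld_decay_bp)
        for i in range(n_founders, n_total):
            s, d = sire_idx[i], dam_idx[i]
            A[i] = _meiosis(rng, A[s], B[s], pos, cfg.recomb_rate)
            B[i] = _meiosis(rng, A[d], B[d], pos, cfg.recomb_rate)
        hapA.append(A)
        hapB.append(B)

    calls = np.concatenate([a + b for a, b in zip(hapA, hapB)], axis=1)
    # drift through the pedigree can fix an allele; drop such SNPs from the
    # panel (a real panel would lose them to the MAF filter anyway)
    poly = calls.min(axis=0) != calls.max(axis=0)
    gt = GenotypeTable(samples=ids, snps=snps.loc[poly].reset_index(drop=True),
                       calls=calls[:, poly])
    ped = PedigreeTable(records=pd.DataFrame({
        "id": ids,
        "sire": [ids[s] if s >= 0 else UNKNOWN_PARENT for s in sire_idx],
        "dam": [ids[d] if d >= 0 else UNKNOWN_PARENT for d in dam_idx],
    }))
    return gt, ped, pd.Series(gen_of, index=ids, name="generation")


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _standardize(calls: np.ndarray):
    f = calls.mean(axis=0) / 2.0
    f = np.clip(f, 1e-6, 1 - 1e-6)
    return (calls - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))


def _scale_to_variance(g: np.ndarray, target: float) -> np.ndarray:
    v = float(np.var(g))
    if v == 0:
        return g
    return g * np.sqrt(target / v)


def simulate_trait(g: GenotypeTable, spec: TraitSpec, seed: int,
                   generation: pd.Series | None = None):
    """Simulate one trait deviation on the given genotypes.

    Phenotypic variance is 1; genetic variance is ``spec.h2``; each declared
    region carries its stated fraction of the genetic variance exactly
    in-sample (effects rescaled after sampling).
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 1)))
    n, m = g.n, g.m
    W = _standardize(g.calls.astype(float))
    f = g.calls.astype(float).mean(axis=0) / 2.0
    maf = np.minimum(f, 1 - f)
    pos = g.snps["pos"].to_numpy()
    chrom = g.snps["chrom"].to_numpy()

    sigma2_g = spec.h2
    beta = np.zeros(m)
    regions = []
    qtl_idx_all: list[int] = []
    used = np.zeros(m, dtype=bool)
    for frac in spec.region_fractions:
        placed = False
        for _ in range(200):
            c = rng.choice(np.unique(chrom))
            on_c = np.flatnonzero(chrom == c)
            start = int(rng.integers(pos[on_c].min(),
                                     max(pos[on_c].max() - spec.region_width_bp, pos[on_c].min()) + 1))
            end = start + spec.region_width_bp
            in_reg = on_c[(pos[on_c] >= start) & (pos[on_c] < end)]
            cand = in_reg[~used[in_reg]]
            if spec.qtl_freq_range is not None:
                flo, fhi = spec.qtl_freq_range
                pref = cand[(maf[cand] >= flo) & (maf[cand] <= fhi)]
                if pref.size >= spec.snps_per_region:
                    cand = pref
            if cand.size >= spec.snps_per_region and not used[in_reg].any():
                placed = True
                break
        if not placed:
            raise ValueError("could not place a QTL region with SNPs on the map")
        qtl = rng.choice(cand, size=spec.snps_per_region, replace=False)
        used[in_reg] = True
        b = rng.normal(size=qtl.size)
        g_reg = W[:, qtl] @ b
        scale = np.sqrt(frac * sigma2_g / max(np.var(g_reg), 1e-12))
        beta[qtl] = b * scale
        qtl_idx_all.extend(qtl.tolist())
        regions.append({"chrom": str(c), "start": int(start), "end": int(end),
                        "snp_indices": np.sort(in_reg).tolist(),
                        "qtl_snps": np.sort(qtl).tolist(), "fraction": float(frac)})

    bg_frac = 1.0 - float(np.sum(spec.region_fractions))
    bg_idx = np.flatnonzero(~used)
    if sigma2_g > 0 and bg_frac > 0 and bg_idx.size:
        b = rng.normal(size=bg_idx.size)
        g_bg = W[:, bg_idx] @ b
        beta[bg_idx] = b * np.sqrt(bg_frac * sigma2_g / max(np.var(g_bg), 1e-12))

    g_true = W @ beta
    var_g = float(np.var(g_true))
    if spec.h2 == 0 or var_g == 0:
        sigma2_e = 1.0
        g_true = np.zeros(n)
        beta[:] = 0.0
        var_g = 0.0
    else:
        sigma2_e = var_g * (1.0 - spec.h2) / spec.h2
    e = rng.normal(size=n)
    e -= e.mean()
    if var_g > 0:
        # orthogonalize the residual in-sample so var(y) = var(g) + var(e)
        e -= g_true * (np.cov(e, g_true, bias=True)[0, 1] / var_g)
    e *= np.sqrt(sigma2_e / np.var(e))
    y = g_true + e

    rec = pd.DataFrame({"id": g.samples, "trait": spec.name, "value": y})
    if generation is not None:
        rec["date"] = generation.reindex(g.samples).to_numpy()
    pheno = PhenotypeTable(records=rec)
    truth = TrueGenetics(
        g_true=pd.Series(g_true, index=g.samples),
        beta=beta, regions=regions, sigma2_g=var_g, sigma2_e=sigma2_e,
        h2=float(var_g / (var_g + sigma2_e)) if var_g + sigma2_e > 0 else 0.0)
    return pheno, truth


# ---------------------------------------------------------------------------
# dataset bundles
# ---------------------------------------------------------------------------

def make_dataset(cfg: SimConfig) -> DatasetBundle:
    """Genotypes + phenotypes + pedigree + truth + date-like split.

    The validation set is the most recent generation; optionally a fraction
    of earlier (training-era) individuals is left ungenotyped so that
    single-step methods have pedigree-only relatives to exploit.
    """
    gt, ped, gen = simulate_genotypes(cfg)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))

    records = []
    truth = {}
    for t_i, spec in enumerate(cfg.traits):
        pheno, tg = simulate_trait(gt, spec, seed=cfg.seed * 1000 + t_i,
                                   generation=gen)
        records.append(pheno.records)
        truth[spec.name] = tg
    phenotypes = PhenotypeTable(records=pd.concat(records, ignore_index=True))

    last_gen = int(gen.max())
    val_mask = (gen == last_gen).to_numpy()
    non_val = np.flatnonzero(~val_mask)
    ungeno = np.zeros(gt.n, dtype=bool)
    if cfg.ungenotyped_fraction > 0:
        k = int(round(cfg.ungenotyped_fraction * non_val.size))
        ungeno[rng.choice(non_val, size=k, replace=False)] = True
    genotyped_idx = np.flatnonzero(~ungeno)
    genotypes = gt.subset(sample_idx=genotyped_idx)

    ids = np.asarray(gt.samples)
    train_ids = ids[~val_mask & ~ungeno].tolist()
    val_ids = ids[val_mask].tolist()
    return DatasetBundle(genotypes=genotypes, phenotypes=phenotypes, pedigree=ped,
                         truth=truth, train_ids=train_ids, val_ids=val_ids,
                         generation=gen, config=cfg)
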