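"""Readers/writers for genotype, phenotype, pedigree and GRM files, plus marker/sample QC.

Supported dialects
------------------
* PLINK ``.bed/.bim/.fam`` (v1 magic bytes, SNP-major) and PLINK ``.raw``
  additive dosage text.
* GCTA GRM text (``i j n_snps value`` triplets, optionally gzipped) and
  binary (``.grm.bin`` float32 lower triangle + ``.grm.id``).
* Phenotype TSV (``id  trait  value  [date]``) holding trait deviations (TD),
  i.e. phenotypes pre-corrected for fixed effects.
* Pedigree CSV (``id,sire,dam``), unknown parent coded ``0``.

Missing genotype calls are stored as ``-1``; QC-surviving tables are
mean-imputed later, when the genotype design matrices are built.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeTable",
    "PhenotypeTable",
    "PedigreeTable",
    "QcReport",
    "read_genotypes",
    "write_genotypes",
    "qc_filter",
    "hwe_exact_pvalue",
    "read_grm",
    "write_grm",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """n x m allele-dosage table with SNP map information.

    ``calls[i, j]`` counts copies of the reference allele of SNP ``j``
    carried by individual ``i`` (0/1/2, ``MISSING`` = -1).
    """

    samples: list[str]
    snps: pd.DataFrame  # columns: snp, chrom, pos, allele
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.snps = self.snps.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        n, m = self.calls.shape
        if n != len(self.samples):
            raise ValueError(f"calls rows ({n}) != samples ({len(self.samples)})")
        if m != len(self.snps):
            raise ValueError(f"calls cols ({m}) != snps ({len(self.snps)})")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,missing}")
        if self.snps["snp"].duplicated().any():
            dup = self.snps.loc[self.snps["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicate SNP identifier: {dup}")
        if (self.snps["pos"].to_numpy() < 0).any():
            raise ValueError("bp positions must be non-negative")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) >= 0):
                raise ValueError("bp positions must be non-decreasing within a chromosome")

    @property
    def n(self) -> int:
        return self.calls.shape[0]

    @property
    def m(self) -> int:
        return self.calls.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Reference-allele frequency per SNP, over non-missing calls."""
        c = self.calls
        obs = c != MISSING
        cnt = obs.sum(axis=0)
        tot = np.where(c == MISSING, 0, c).sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = tot / (2.0 * cnt)
        return np.where(cnt == 0, np.nan, f)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeTable":
        si = np.arange(self.n) if sample_idx is None else np.asarray(sample_idx)
        sj = np.arange(self.m) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeTable(
            samples=[self.samples[i] for i in si],
            snps=self.snps.iloc[sj].reset_index(drop=True),
            calls=self.calls[np.ix_(si, sj)].copy(),
        )


@dataclass
class PhenotypeTable:
    """Long-format trait deviations: one value per (sample, trait)."""

    records: pd.DataFrame  # columns: id, trait, value[, date]

    def __post_init__(self) -> None:
        df = self.records
        need = {"id", "trait", "value"}
        if not need.issubset(df.columns):
            raise ValueError(f"phenotype table needs columns {sorted(need)}")
        if df.duplicated(["id", "trait"]).any():
            raise ValueError("one value per (sample, trait) required")
        vals = pd.to_numeric(df["value"], errors="raise").astype(float)
        if not np.isfinite(vals).all():
            raise ValueError("phenotype values must be finite")
        self.records = df.assign(value=vals).reset_index(drop=True)

    def trait(self, name: str) -> pd.Series:
        sub = self.records[self.records["trait"] == name]
        return pd.Series(sub["value"].to_numpy(), index=sub["id"].to_numpy())

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.records["trait"]))


UNKNOWN_PARENT = "0"


@dataclass
class PedigreeTable:
    """3-column pedigree; unknown parent coded '0'."""

    records: pd.DataFrame  # columns: id, sire, dam

    def __post_init__(self) -> None:
        df = self.records.astype({"id": str, "sire": str, "dam": str})
        if df["id"].duplicated().any():
            raise ValueError("duplicate individual in pedigree")
        self.records = df.reset_index(drop=True)
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        """Kahn topological sort: parents before offspring."""
        ids = self.records["id"].tolist()
        idx = {v: i for i, v in enumerate(ids)}
        children: dict[int, list[int]] = {i: [] for i in range(len(ids))}
        indeg = np.zeros(len(ids), dtype=int)
        for i, (s, d) in enumerate(zip(self.records["sire"], self.records["dam"])):
            for p in (s, d):
                if p != UNKNOWN_PARENT:
                    if p not in idx:
                        raise ValueError(f"parent {p} not in pedigree")
                    children[idx[p]].append(i)
                    indeg[i] += 1
        order: list[int] = [i for i in range(len(ids)) if indeg[i] == 0]
        head = 0
        while head < len(order):
            for c in children[order[head]]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
            head += 1
        if len(order) < len(ids):
            raise ValueError("pedigree contains a cycle")
        return [ids[i] for i in order]


@dataclass
class QcReport:
    n_samples_in: int
    n_snps_in: int
    samples_removed_callrate: int = 0
    snps_removed_callrate: int = 0
    snps_removed_hwe: int = 0
    snps_removed_maf: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0
    removed_snp_ids: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_samples_in - self.samples_removed_callrate != self.n_samples_out:
            raise AssertionError("sample counts do not reconcile")
        removed = (
            self.snps_removed_callrate + self.snps_removed_hwe + self.snps_removed_maf
        )
        if self.n_snps_in - removed != self.n_snps_out:
            raise AssertionError("SNP counts do not reconcile")


# ---------------------------------------------------------------------------
# genotype IO
# ---------------------------------------------------------------------------

def read_genotypes(path: str, dialect: str = "bed-bim-fam") -> GenotypeTable:
    """Read a genotype file set.

    ``path`` is the file-set prefix for ``bed-bim-fam`` and the ``.raw``
    file path for ``raw-additive``.
    """
    if dialect == "bed-bim-fam":
        return _read_bed(path)
    if dialect == "raw-additive":
        return _read_raw(path)
    raise ValueError(f"unknown dialect: {dialect}")


def write_genotypes(g: GenotypeTable, path: str, dialect: str = "bed-bim-fam") -> None:
    if dialect == "bed-bim-fam":
        _write_bed(g, path)
    elif dialect == "raw-additive":
        _write_raw(g, path)
    else:
        raise ValueError(f"unknown dialect: {dialect}")


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> reference (A1) allele dosage
_BED_CODE_TO_DOSE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSE_TO_BED_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


def _read_bed(prefix: str) -> GenotypeTable:
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    samples = fam["iid"].tolist()
    n, m = len(samples), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(".bed magic bytes missing or not SNP-major")
    bps = (n + 3) // 4  # bytes per SNP block
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bps * m:
        raise ValueError(
            f".bed size mismatch: expected {bps * m} data bytes for "
            f"{n} samples x {m} SNPs, found {body.size}")
    blocks = body.reshape(m, bps)
    # unpack 2-bit fields, little-endian within byte
    shifts = np.arange(4) * 2
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bps * 4)[:, :n]
    calls = _BED_CODE_TO_DOSE[codes].T
    snps = pd.DataFrame({"snp": bim["snp"], "chrom": bim["chrom"],
                         "pos": bim["pos"].astype(int), "allele": bim["a1"]})
    return GenotypeTable(samples=samples, snps=snps, calls=calls)


def _write_bed(g: GenotypeTable, prefix: str) -> None:
    n, m = g.n, g.m
    fam = pd.DataFrame({"fid": g.samples, "iid": g.samples, "pat": "0",
                        "mat": "0", "sex": "0", "pheno": "-9"})
    fam.to_csv(prefix + ".fam", sep=" ", header=False, index=False)
    bim = pd.DataFrame({"chrom": g.snps["chrom"], "snp": g.snps["snp"], "cm": 0,
                        "pos": g.snps["pos"], "a1": g.snps["allele"], "a2": "N"})
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    code = np.empty((m, n), dtype=np.uint8)
    for dose, c in _DOSE_TO_BED_CODE.items():
        code[g.calls.T == dose] = c
    bps = (n + 3) // 4
    padded = np.zeros((m, bps * 4), dtype=np.uint8)
    padded[:, :n] = code
    padded[:, n:] = 1  # pad bits read back as missing and are dropped
    shifts = np.arange(4) * 2
    packed = (padded.reshape(m, bps, 4) << shifts[None, None, :]).sum(axis=2)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def _read_raw(path: str, map_path: str | None = None) -> GenotypeTable:
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in meta:
        raise ValueError(".raw file lacks IID column")
    snp_cols = [c for c in df.columns if c not in meta]
    ids, alleles = [], []
    for c in snp_cols:
        if "_" in c:
            sid, allele = c.rsplit("_", 1)
        else:
            sid, allele = c, "A"
        ids.append(sid)
        alleles.append(allele)
    vals = df[snp_cols].replace("NA", str(MISSING)).to_numpy(dtype=float)
    if not np.isin(vals, (0, 1, 2, MISSING)).all():
        raise ValueError("unknown dosage code in .raw file")
    # .raw carries no map; positions default to panel order on one chromosome
    snps = pd.DataFrame({"snp": ids, "chrom": "1",
                         "pos": np.arange(1, len(ids) + 1), "allele": alleles})
    if map_path is not None:
        mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                         names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str, "snp": str})
        snps = snps.drop(columns=["chrom", "pos"]).merge(mp[["snp", "chrom", "pos"]], on="snp")
        snps = snps[["snp", "chrom", "pos", "allele"]]
    return GenotypeTable(samples=df["IID"].tolist(), snps=snps,
                         calls=vals.astype(np.int8))


def _write_raw(g: GenotypeTable, path: str) -> None:
    cols = [f"{s}_{a}" for s, a in zip(g.snps["snp"], g.snps["allele"])]
    body = pd.DataFrame(g.calls.astype(object), columns=cols)
    body = body.where(g.calls != MISSING, "NA")
    out = pd.concat(
        [pd.DataFrame({"FID": g.samples, "IID": g.samples, "PAT": "0", "MAT": "0",
                       "SEX": "0", "PHENOTYPE": "-9"}), body], axis=1)
    out.to_csv(path, sep=" ", index=False)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, no mid-p).

    Sums the conditional probabilities, given the minor-allele count, of all
    heterozygote counts no more probable than the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(n_het = h | n_minor) up to a constant
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    logp = (-gammaln(hets + 1) - gammaln(hom_min + 1) - gammaln(hom_maj + 1)
            + hets * np.log(2.0))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def qc_filter(
    g: GenotypeTable,
    min_snp_call: float = 0.95,
    min_sample_call: float = 0.90,
    hwe_alpha: float = 0.001,
    min_maf: float = 0.01,
) -> tuple[GenotypeTable, QcReport]:
    """Marker/sample QC with a fixed filter order.

    1. sample call rate (> ``min_sample_call``),
    2. SNP call rate (>= ``min_snp_call``),
    3. exact HWE test (p >= ``hwe_alpha`` retained),
    4. MAF strictly above ``min_maf`` (on surviving samples).
    """
    if g.n == 0 or g.m == 0:
        raise ValueError("empty genotype table")
    rep = QcReport(n_samples_in=g.n, n_snps_in=g.m)

    obs = g.calls != MISSING
    keep_s = obs.mean(axis=1) > min_sample_call
    # equality counts as passing for samples stated as "above 90%"
    rep.samples_removed_callrate = int((~keep_s).sum())
    g = g.subset(sample_idx=np.flatnonzero(keep_s))

    obs = g.calls != MISSING
    keep_call = obs.mean(axis=0) >= min_snp_call
    rep.snps_removed_callrate = int((~keep_call).sum())
    rep.removed_snp_ids["call_rate"] = g.snps.loc[~keep_call, "snp"].tolist()
    g = g.subset(snp_idx=np.flatnonzero(keep_call))

    pvals = np.ones(g.m)
    for j in range(g.m):
        col = g.calls[:, j]
        col = col[col != MISSING]
        pvals[j] = hwe_exact_pvalue(
            int((col == 1).sum()), int((col == 2).sum()), int((col == 0).sum()))
    keep_hwe = pvals >= hwe_alpha
    rep.snps_removed_hwe = int((~keep_hwe).sum())
    rep.removed_snp_ids["hwe"] = g.snps.loc[~keep_hwe, "snp"].tolist()
    g = g.subset(snp_idx=np.flatnonzero(keep_hwe))

    f = g.allele_freq()
    maf = np.minimum(f, 1 - f)
    keep_maf = maf > min_maf
    rep.snps_removed_maf = int((~keep_maf).sum())
    rep.removed_snp_ids["maf"] = g.snps.loc[~keep_maf, "snp"].tolist()
    g = g.subset(snp_idx=np.flatnonzero(keep_maf))

    if g.m == 0:
        raise ValueError("QC removed every SNP")
    rep.n_samples_out, rep.n_snps_out = g.n, g.m
    rep.validate()
    return g, rep


# ---------------------------------------------------------------------------
# GRM IO (GCTA dialects)
# ---------------------------------------------------------------------------

def write_grm(values: np.ndarray, ids: list[str], prefix: str,
              dialect: str = "gcta-text", n_snps: int = 0) -> None:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("GRM must be square")
    if len(ids) != values.shape[0]:
        raise ValueError("id count does not match GRM dimension")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    n = values.shape[0]
    pd.DataFrame({"fid": ids, "iid": ids}).to_csv(
        prefix + ".grm.id", sep="\t", header=False, index=False)
    tri = [(i + 1, j + 1, values[i, j]) for i in range(n) for j in range(i + 1)]
    if dialect == "gcta-text":
        with gzip.open(prefix + ".grm.gz", "wt") as fh:
            for i, j, v in tri:
                fh.write(f"{i}\t{j}\t{n_snps}\t{v:.6f}\n")
    elif dialect == "gcta-binary":
        lower = np.array([v for _, _, v in tri], dtype=np.float32)
        lower.tofile(prefix + ".grm.bin")
        np.full(lower.size, float(n_snps), dtype=np.float32).tofile(prefix + ".grm.N.bin")
    else:
        raise ValueError(f"unknown dialect: {dialect}")


def read_grm(prefix: str, dialect: str = "gcta-text") -> tuple[np.ndarray, list[str]]:
    ids_df = pd.read_csv(prefix + ".grm.id", sep="\t", header=None, dtype=str)
    ids = ids_df.iloc[:, 1].tolist()
    n = len(ids)
    values = np.zeros((n, n))
    if dialect == "gcta-text":
        df = pd.read_csv(prefix + ".grm.gz", sep="\t", header=None,
                         names=["i", "j", "nsnp", "v"])
        i = df["i"].to_numpy(int) - 1
        j = df["j"].to_numpy(int) - 1
        values[i, j] = df["v"].to_numpy()
        values[j, i] = df["v"].to_numpy()
    elif dialect == "gcta-binary":
        lower = np.fromfile(prefix + ".grm.bin", dtype=np.float32)
        expected = n * (n + 1) // 2
        if lower.size != expected:
            raise ValueError(
                f"truncated .grm.bin: {lower.size} entries, expected {expected}")
        k = 0
        for i in range(n):
            values[i, : i + 1] = lower[k: k + i + 1]
            k += i + 1
        values = values + np.tril(values, -1).T
    else:
        raise ValueError(f"unknown dialect: {dialect}")
    return values, ids


# ---------------------------------------------------------------------------
# phenotype / pedigree IO
# ---------------------------------------------------------------------------

def read_phenotypes(path: str) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "trait": str})
    return PhenotypeTable(records=df)


def write_phenotypes(p: PhenotypeTable, path: str) -> None:
    p.records.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str) -> PedigreeTable:
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.lower() for c in df.columns]
    return PedigreeTable(records=df[["id", "sire", "dam"]])


def write_pedigree(p: PedigreeTable, path: str) -> None:
    p.records.to_csv(path, index=False)
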