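"""Data model and file I/O.

Genotype matrices move through the pipeline as dense dosage arrays with a
SNP metadata table. On disk the package speaks PLINK-1 bed/bim/fam
(bit-exact 2-bit decoding, SNP-major), dosage TSV, GMT gene sets, gene
coordinate TSV (1-based inclusive), and the GCTA gzipped lower-triangle
GRM text format.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "GenotypeMatrix",
    "PathwayDB",
    "read_genotypes",
    "write_genotypes",
    "read_gene_table",
    "write_gene_table",
    "read_gmt",
    "write_gmt",
    "read_grm",
    "write_grm",
    "qc_filter",
    "map_snps_to_genes",
    "prune_related",
]

SNP_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2"]
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
MISSING = np.nan


@dataclass
class GenotypeMatrix:
    """n x m dosage matrix with per-SNP metadata.

    Dosages count copies of allele1 (the effect allele) and lie in [0, 2];
    missing values are NaN. ``snps`` is a DataFrame with columns
    snp_id, chrom, pos, a1, a2 and optionally maf, info.
    """

    dosages: np.ndarray
    iids: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ParameterError("dosages must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        if len(self.iids) != n:
            raise FormatError("individual ID count does not match dosage rows")
        if len(self.snps) != m:
            raise FormatError("SNP metadata row count does not match dosage columns")
        if len(set(self.iids)) != n:
            raise FormatError("duplicated individual IDs")
        if self.snps["snp_id"].duplicated().any():
            raise FormatError("duplicated SNP IDs")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Sample minor allele frequency per SNP (missing ignored)."""
        p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1 - p)

    def imputed(self) -> "GenotypeMatrix":
        """Copy with missing dosages replaced by the per-SNP observed mean."""
        X = self.dosages
        if not np.isnan(X).any():
            return self
        X = X.copy()
        col_mean = np.nanmean(X, axis=0)
        r, c = np.nonzero(np.isnan(X))
        X[r, c] = col_mean[c]
        return GenotypeMatrix(X, list(self.iids), self.snps.copy())

    def standardized(self) -> np.ndarray:
        """Mean-imputed, (x - 2p)/sqrt(2p(1-p)) standardized dosages."""
        X = self.imputed().dosages
        p = X.mean(axis=0) / 2.0
        denom = np.sqrt(2 * p * (1 - p))
        denom[denom == 0] = 1.0
        return (X - 2 * p) / denom

    def subset_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(list(idx), dtype=int)
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.iids), self.snps.iloc[idx].copy()
        )

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(list(idx), dtype=int)
        return GenotypeMatrix(
            self.dosages[idx, :], [self.iids[i] for i in idx], self.snps.copy()
        )


@dataclass
class PathwayDB:
    """Named gene sets with an optional per-pathway source label."""

    pathways: dict[str, set[str]]
    sources: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.pathways.items())

    def __len__(self) -> int:
        return len(self.pathways)

    def genes(self, name: str) -> set[str]:
        return self.pathways[name]

    def source(self, name: str) -> str:
        return self.sources.get(name, "custom")


# ---------------------------------------------------------------------------
# PLINK-1 triplet


def write_genotypes(geno: GenotypeMatrix, prefix) -> None:
    """Write a PLINK-1 bed/bim/fam triplet (hard calls; dosages rounded)."""
    prefix = Path(prefix)
    snps = geno.snps
    bim = pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "snp_id": snps["snp_id"],
            "cm": 0,
            "pos": snps["pos"],
            "a1": snps["a1"],
            "a2": snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": geno.iids,
            "iid": geno.iids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    X = geno.dosages
    n, m = X.shape
    n_bytes = (n + 3) // 4
    # dosage (count of a1) -> 2-bit code: 2 -> 00, 1 -> 10, 0 -> 11, NaN -> 01
    rounded = np.clip(np.round(X), 0, 2)
    code = np.full(X.shape, 3, dtype=np.uint8)
    code[rounded == 2] = 0
    code[rounded == 1] = 2
    code[rounded == 0] = 3
    code[np.isnan(X)] = 1
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros((m, n_bytes), dtype=np.uint8)
        for shift in range(4):
            idx = np.arange(shift, n, 4)
            block = code[idx, :].T  # m x len(idx)
            buf[:, : block.shape[1]] |= block << (2 * shift)
        fh.write(buf.tobytes())


def read_genotypes(path) -> GenotypeMatrix:
    """Read a PLINK-1 triplet prefix or a dosage TSV into a GenotypeMatrix.

    A path ending in .tsv (or .txt) is parsed as a dosage table: columns
    snp_id, chrom, pos, a1, a2 then one column per individual. Otherwise the
    path is treated as a PLINK prefix. Missing genotypes come back as NaN.
    """
    path = Path(path)
    if path.suffix in {".tsv", ".txt"}:
        return _read_dosage_tsv(path)
    return _read_plink(path)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"dosage TSV lacks columns {missing_cols}")
    iids = [c for c in df.columns if c not in SNP_COLUMNS]
    if not iids:
        raise FormatError("dosage TSV has no individual columns")
    snps = df[SNP_COLUMNS].copy()
    X = df[iids].to_numpy(dtype=float).T
    return GenotypeMatrix(X, iids, snps)


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    df = geno.snps[SNP_COLUMNS].copy()
    for i, iid in enumerate(geno.iids):
        df[iid] = geno.dosages[i, :]
    df.to_csv(path, sep="\t", index=False)


def _read_plink(prefix: Path) -> GenotypeMatrix:
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    bed_path = prefix.with_suffix(".bed")
    for p in (bim_path, fam_path, bed_path):
        if not p.exists():
            raise FormatError(f"missing PLINK file {p}")
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    bad = ~bim["a1"].str.fullmatch(r"[ACGT0]") | ~bim["a2"].str.fullmatch(r"[ACGT0]")
    if bad.any():
        raise FormatError(
            f"unknown allele codes in bim: {bim.loc[bad, 'snp_id'].tolist()[:5]}"
        )
    n, m = len(fam), len(bim)
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError("bed file magic bytes absent or not SNP-major")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * n_bytes:
        raise FormatError(
            f"bed payload size {body.size} != expected {m * n_bytes} "
            "(bim/fam/bed row-count mismatch)"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    codes = codes[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])  # 00, 01, 10, 11 -> a1 dosage
    X = lut[codes].T
    snps = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(X, fam["iid"].tolist(), snps)


# ---------------------------------------------------------------------------
# Gene tables, GMT, GRM text


def read_gene_table(path) -> pd.DataFrame:
    """Gene coordinate TSV: gene_id, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"gene table must have columns {sorted(required)}")
    if (df["start"] > df["end"]).any():
        raise FormatError("gene table has start > end")
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes[["gene_id", "chrom", "start", "end"]].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> PathwayDB:
    """GMT: tab-separated lines of name, description/source, genes..."""
    pathways: dict[str, set[str]] = {}
    sources: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line with fewer than 3 fields: {line[:60]}")
            name, source = parts[0], parts[1]
            pathways[name] = set(g for g in parts[2:] if g)
            sources[name] = source
    return PathwayDB(pathways=pathways, sources=sources)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for name, genes in db.pathways.items():
            fields = [name, db.source(name)] + sorted(genes)
            fh.write("\t".join(fields) + "\n")


def write_grm(grm, prefix) -> None:
    """GCTA text GRM: gzipped lower triangle (i, j, n_snps, value) + .id."""
    from .vc import GRM  # local import to avoid cycle

    assert isinstance(grm, GRM)
    prefix = Path(prefix)
    with gzip.open(str(prefix) + ".grm.gz", "wt") as fh:
        A = grm.values
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps}\t{A[i, j]:.8g}\n")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix):
    from .vc import GRM

    prefix = Path(prefix)
    ids = []
    with open(str(prefix) + ".grm.id") as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
    n = len(ids)
    A = np.zeros((n, n))
    n_snps = 0
    with gzip.open(str(prefix) + ".grm.gz", "rt") as fh:
        for line in fh:
            i, j, m, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            A[i, j] = A[j, i] = float(v)
            n_snps = int(m)
    return GRM(values=A, ids=ids, n_snps=n_snps)


# ---------------------------------------------------------------------------
# QC, annotation, relatedness pruning


def qc_filter(snps: pd.DataFrame, maf_min: float, info_min: float) -> np.ndarray:
    """Indices of SNPs passing maf >= maf_min AND info >= info_min (inclusive).

    Expects columns ``maf`` and ``info``. Emits a warning (and returns an
    empty index array) when nothing survives.
    """
    if not (0 <= maf_min <= 1 and 0 <= info_min <= 1):
        raise ParameterError("QC thresholds must lie in [0, 1]")
    keep = (snps["maf"].to_numpy() >= maf_min) & (snps["info"].to_numpy() >= info_min)
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        warnings.warn("qc_filter removed every SNP", stacklevel=2)
    return idx


def map_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, window_kb: float = 0.0
) -> dict[str, np.ndarray]:
    """Map SNPs to genes by position overlap with an optional flanking window.

    SNP s belongs to gene g iff chromosomes match and
    start - window <= pos(s) <= end + window (1-based inclusive, window in
    kb). A SNP may land in several genes. Returns gene_id -> sorted array of
    SNP column indices; genes with no SNPs are omitted.
    """
    if window_kb < 0:
        raise ParameterError("window_kb must be >= 0")
    window = int(round(window_kb * 1000))
    pos = snps["pos"].to_numpy()
    chrom = snps["chrom"].astype(str).to_numpy()
    out: dict[str, np.ndarray] = {}
    for row in genes.itertuples(index=False):
        mask = (
            (chrom == str(row.chrom))
            & (pos >= row.start - window)
            & (pos <= row.end + window)
        )
        idx = np.nonzero(mask)[0]
        if idx.size:
            out[str(row.gene_id)] = idx
    return out


def pathway_snp_indices(
    db: PathwayDB, gene_map: dict[str, np.ndarray], pathway: str
) -> np.ndarray:
    """Union of SNP indices over a pathway's mapped genes, sorted."""
    idx: set[int] = set()
    for g in db.genes(pathway):
        if g in gene_map:
            idx.update(int(i) for i in gene_map[g])
    return np.array(sorted(idx), dtype=int)


def prune_related(grm, cutoff: float = 0.025) -> np.ndarray:
    """Greedy relatedness pruning: keep a maximal set with all pairs <= cutoff.

    Repeatedly drops the individual involved in the most offending pairs
    (ties: higher mean relatedness, then later ID order), which approximates
    maximising the retained sample. Returns sorted indices of kept
    individuals; the result is verified to contain no offending pair.
    """
    if cutoff <= 0:
        raise ParameterError("relatedness cutoff must be positive")
    A = grm.values if hasattr(grm, "values") else np.asarray(grm, dtype=float)
    n = A.shape[0]
    off = A.copy()
    np.fill_diagonal(off, -np.inf)
    alive = np.ones(n, dtype=bool)
    offending = off > cutoff
    while True:
        counts = (offending & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = 0
        worst = counts.max()
        if worst == 0:
            break
        cand = np.nonzero(counts == worst)[0]
        if cand.size > 1:
            with np.errstate(invalid="ignore"):
                means = np.array(
                    [off[i, alive & (np.arange(n) != i)].mean() for i in cand]
                )
            cand = cand[means == means.max()]
        alive[cand[-1]] = False  # later ID order breaks remaining ties
    kept = np.nonzero(alive)[0]
    sub = A[np.ix_(kept, kept)].copy()
    np.fill_diagonal(sub, 0.0)
    assert sub.max(initial=0.0) <= cutoff + 1e-12
    return kept
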