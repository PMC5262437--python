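"""Stage-2 multilevel regional heritability.

Pathway-level two-GRM partitioned fits, gene-level fits, fixed-size block
scans across genes, and circular-permutation empirical nulls that rotate a
SNP index set along the panel while preserving its size and spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, ParameterError
from .pathway import bonferroni
from .vc import grm_from_standardized, lrt_p, reml_fit

__all__ = [
    "Partition",
    "RegionalResult",
    "CircularNull",
    "partition_by_pathway",
    "fit_region_h2",
    "make_blocks",
    "scan_gene",
    "circular_null",
    "percent_of_panel",
]


def percent_of_panel(n_region: int, n_panel: int, decimals: int = 2) -> float:
    """%SNP column arithmetic: 100 * n_region / n_panel, rounded."""
    if n_panel <= 0 or n_region < 0 or n_region > n_panel:
        raise ParameterError("need 0 <= n_region <= n_panel, n_panel > 0")
    return round(100.0 * n_region / n_panel, decimals)


@dataclass
class Partition:
    """Region / complement split of the analysis SNP panel."""

    region: np.ndarray
    complement: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=int)
        self.complement = np.asarray(self.complement, dtype=int)
        if np.intersect1d(self.region, self.complement).size:
            raise ParameterError("region and complement overlap")

    @property
    def n_panel(self) -> int:
        return self.region.size + self.complement.size


@dataclass
class RegionalResult:
    name: str
    h2_region: float
    se_region: float
    h2_comp: float
    se_comp: float
    lrt_stat: float
    p_lrt: float
    n_region_snps: int
    n_panel_snps: int
    loglik_full: float
    loglik_null: float
    converged: bool
    pct_snp: float = field(init=False)
    pct_h2: float = field(init=False)
    enrichment_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.pct_snp = percent_of_panel(self.n_region_snps, self.n_panel_snps)
        total_g = self.h2_region + self.h2_comp
        self.pct_h2 = 100.0 * self.h2_region / total_g if total_g > 0 else 0.0
        self.enrichment_ratio = (
            self.pct_h2 / self.pct_snp if self.pct_snp > 0 else np.nan
        )


@dataclass
class CircularNull:
    n_perm: int
    offsets: np.ndarray
    null_values: np.ndarray
    observed: float
    p_perm: float


def partition_by_pathway(snps: pd.DataFrame, gene_map, pathway_db, pathway: str) -> Partition:
    """Split the SNP panel into a pathway's SNPs and the rest.

    ``gene_map`` maps gene_id -> panel SNP indices (data_model_io
    map_snps_to_genes output). Raises when the region is empty; a region
    covering the whole panel is returned with ``degenerate=True``.
    """
    idx: set[int] = set()
    for g in pathway_db.genes(pathway):
        if g in gene_map:
            idx.update(int(i) for i in gene_map[g])
    region = np.array(sorted(idx), dtype=int)
    if region.size == 0:
        raise AnalysisError(f"pathway {pathway!r} maps to zero panel SNPs")
    m = len(snps)
    complement = np.setdiff1d(np.arange(m), region)
    return Partition(
        region=region, complement=complement, degenerate=complement.size == 0
    )


def fit_region_h2(
    genotypes,
    y,
    covariates,
    partition: Partition,
    name: str = "",
    Z: np.ndarray | None = None,
) -> RegionalResult:
    """Joint REML with a region GRM and a complement GRM.

    p_lrt comes from dropping the region component against the
    complement-only null (boundary 50:50 chi-square mixture). The %h2 share
    is 100 * hR2 / (hR2 + hC2) and the enrichment ratio is %h2 / %SNP. A
    precomputed standardized matrix ``Z`` avoids re-standardizing during
    scans.
    """
    if partition.degenerate:
        raise AnalysisError("degenerate partition: complement is empty")
    if Z is None:
        Z = genotypes.standardized()
    ids = list(genotypes.iids) if genotypes is not None else [
        str(i) for i in range(Z.shape[0])
    ]
    grm_r = grm_from_standardized(Z[:, partition.region], ids)
    grm_c = grm_from_standardized(Z[:, partition.complement], ids)
    null = reml_fit(y, covariates, [grm_c], names=["comp"])
    full = reml_fit(y, covariates, [grm_r, grm_c], names=["region", "comp"])
    if full.loglik < null.loglik:
        # retry from the null solution so the nested fit can't end up worse
        warm = np.array([0.0, null.variance("comp"), null.variance("e")])
        retry = reml_fit(
            y, covariates, [grm_r, grm_c], names=["region", "comp"], start=warm
        )
        if retry.loglik > full.loglik:
            full = retry
    stat, p = lrt_p(full.loglik, null.loglik, tol=1e-2)
    return RegionalResult(
        name=name,
        h2_region=full.proportion("region"),
        se_region=full.se_of("region") / max(np.sum(full.variances), 1e-300),
        h2_comp=full.proportion("comp"),
        se_comp=full.se_of("comp") / max(np.sum(full.variances), 1e-300),
        lrt_stat=stat,
        p_lrt=p,
        n_region_snps=partition.region.size,
        n_panel_snps=partition.n_panel,
        loglik_full=full.loglik,
        loglik_null=null.loglik,
        converged=full.converged and null.converged,
    )


def make_blocks(gene_snps, window_n: int) -> list[np.ndarray]:
    """Consecutive non-overlapping windows of ``window_n`` SNPs, in genomic
    order; the final remainder (>= 1 SNP) forms the last block."""
    gene_snps = np.asarray(gene_snps, dtype=int)
    if gene_snps.size == 0:
        raise AnalysisError("gene has no SNPs")
    if window_n < 2:
        raise ParameterError("window_n must be >= 2")
    gene_snps = np.sort(gene_snps)
    return [gene_snps[i : i + window_n] for i in range(0, gene_snps.size, window_n)]


def scan_gene(
    genotypes,
    y,
    covariates,
    blocks: list[np.ndarray],
    Z: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Regional-heritability scan: one two-GRM fit per block.

    Region = the block's SNPs, complement = all other panel SNPs. Bonferroni
    across the scan's blocks. Per-block failures are recorded (NaN row) and
    the scan continues.
    """
    if not blocks:
        raise AnalysisError("no blocks supplied")
    if Z is None:
        Z = genotypes.standardized()
    if positions is None:
        positions = genotypes.snps["pos"].to_numpy()
    m = Z.shape[1]
    rows = []
    for b, idx in enumerate(blocks, start=1):
        part = Partition(region=idx, complement=np.setdiff1d(np.arange(m), idx))
        try:
            res = fit_region_h2(genotypes, y, covariates, part, name=f"block{b}", Z=Z)
            rows.append(
                (
                    b,
                    int(positions[idx].min()),
                    int(positions[idx].max()),
                    idx.size,
                    res.h2_region,
                    res.se_region,
                    res.p_lrt,
                )
            )
        except (AnalysisError, np.linalg.LinAlgError):
            rows.append((b, int(positions[idx].min()), int(positions[idx].max()),
                         idx.size, np.nan, np.nan, np.nan))
    out = pd.DataFrame(
        rows, columns=["block", "start_bp", "end_bp", "n_snps", "h2", "se", "p"]
    )
    out["p_bonf"] = bonferroni(out["p"].fillna(1.0).to_numpy(), len(blocks))
    out.loc[out["p"].isna(), "p_bonf"] = np.nan
    return out


def circular_null(
    panel_size: int,
    region: np.ndarray,
    statistic_fn,
    n_perm: int = 1000,
    seed: int = 0,
) -> CircularNull:
    """Circular-permutation null for a region statistic.

    Each permutation rotates every region index by one shared offset
    k ~ Uniform{1..m-1} modulo m, preserving the set's size and inter-SNP
    spacing on the (chromosome, position)-ordered panel. p_perm =
    (r + 1)/(n_perm + 1) with r = #{null statistic >= observed}.
    """
    region = np.asarray(region, dtype=int)
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    if region.size >= panel_size:
        raise AnalysisError("region covers the whole panel; null undefined")
    rng = np.random.default_rng(seed)
    observed = float(statistic_fn(region))
    offsets = rng.integers(1, panel_size, size=n_perm)
    null_values = np.empty(n_perm)
    for i, k in enumerate(offsets):
        null_values[i] = statistic_fn((region + int(k)) % panel_size)
    r = int((null_values >= observed).sum())
    return CircularNull(
        n_perm=n_perm,
        offsets=offsets,
        null_values=null_values,
        observed=observed,
        p_perm=(r + 1) / (n_perm + 1),
    )
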