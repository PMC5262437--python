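"""Two-stage pipeline orchestration.

Stage 1 tests every pathway with the configured engine (genotype-based
permutation test or summary-statistic enrichment), stage 2 runs pathway /
gene / block regional-heritability fits for the stage-1 significant set,
and the PRS stage sweeps cutoffs x clumping x bins for the whole genome
and the candidate pathway. Everything is driven by one config and one
seed; report tables are plain TSV with fixed schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as phio
from . import pathway as pw
from . import prs as prsmod
from . import regional as reg
from . import synthetic as syn
from .errors import ConfigurationError
from .vc import compute_grm

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "RunContext",
    "prepare_context",
    "run_stage1",
    "run_stage2",
    "run_prs",
    "write_reports",
    "run_all",
    "replication_n_bonf",
]

STAGE1_COLUMNS = [
    "rank",
    "database",
    "pathway",
    "p",
    "p_fdr",
    "eff_gene_size",
    "exp_count",
    "obs_count",
]


def replication_n_bonf(pathways_forward: int, datasets: int, pathways_reverse: int) -> int:
    """Replication test-ledger Bonferroni count: forward x datasets + reverse."""
    n = pathways_forward * datasets + pathways_reverse
    if n < 1:
        raise ConfigurationError("replication ledger yields n_bonf < 1")
    return n


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: syn.SimConfig | None = None
    genotypes_path: str | None = None
    summary_path: str | None = None
    genes_path: str | None = None
    gmt_path: str | None = None
    phenotype_path: str | None = None
    engine: str = "genotype"  # or "summary"
    maf_min: float = 0.01
    info_min: float = 0.8
    grm_cutoff: float = 0.025
    window_kb: float = 0.0
    fdr_level: float = 0.05
    n_perm_stage1: int = 999
    magenta_cutoff_pct: float = 95.0
    magenta_n_null: int = 1000
    window_n: int = 200
    n_perm_circular: int = 100
    run_circular: bool = False
    run_scans: bool = True
    prs: prsmod.PRSConfig = field(default_factory=prsmod.PRSConfig)
    prs_clump_settings: tuple[bool, ...] = (False,)
    candidate_pathway: str | None = None
    pathways_forward: int = 4
    datasets: int = 1
    pathways_reverse: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        prs_raw = raw.pop("prs", None)
        cfg = cls(**raw)
        if sim is not None:
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            cfg.simulate = syn.SimConfig(**sim)
        if prs_raw is not None:
            for key in ("p_cutoffs", "bins"):
                if key in prs_raw:
                    prs_raw[key] = tuple(prs_raw[key])
            cfg.prs = prsmod.PRSConfig(**prs_raw)
        return cfg


@dataclass
class RunContext:
    config: PipelineConfig
    genotypes: phio.GenotypeMatrix
    phenotype: np.ndarray
    covariates: pd.DataFrame
    summary: pd.DataFrame | None
    genes: pd.DataFrame
    pathway_db: phio.PathwayDB
    gene_map: dict[str, np.ndarray]
    log: list[str] = field(default_factory=list)

    def note(self, msg: str) -> None:
        self.log.append(msg)


@dataclass
class ReportBundle:
    stage1: pd.DataFrame | None = None
    stage2_pathway: pd.DataFrame | None = None
    stage2_gene: pd.DataFrame | None = None
    stage2_blocks: pd.DataFrame | None = None
    prs_logistic: pd.DataFrame | None = None
    prs_lmm: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)


def prepare_context(config: PipelineConfig) -> RunContext:
    """Load or simulate inputs, apply QC and relatedness pruning."""
    log: list[str] = [f"seed={config.seed}", f"engine={config.engine}"]
    if config.simulate is not None:
        panel, cohort, summary = syn.simulate_all(config.simulate)
        geno = cohort.genotypes
        phe = cohort.phenotype
        cov = cohort.covariates
        genes = panel.genes
        db = panel.pathway_db
        log.append(f"simulated n={geno.n} m={geno.m}")
    else:
        if not (config.genotypes_path and config.genes_path and config.gmt_path):
            raise ConfigurationError(
                "non-simulate mode needs genotypes_path, genes_path, gmt_path"
            )
        geno = phio.read_genotypes(config.genotypes_path)
        genes = phio.read_gene_table(config.genes_path)
        db = phio.read_gmt(config.gmt_path)
        summary = (
            pd.read_csv(config.summary_path, sep="\t")
            if config.summary_path
            else None
        )
        if config.phenotype_path:
            ph = pd.read_csv(config.phenotype_path, sep="\t")
            order = {iid: i for i, iid in enumerate(geno.iids)}
            ph = ph.sort_values("iid", key=lambda s: s.map(order))
            phe = ph["phenotype"].to_numpy()
            cov_cols = [c for c in ph.columns if c not in ("iid", "phenotype")]
            cov = ph[cov_cols].reset_index(drop=True)
        else:
            phe = np.zeros(geno.n, dtype=int)
            cov = pd.DataFrame(index=range(geno.n))
        log.append(f"loaded n={geno.n} m={geno.m}")

    n_before = geno.n
    grm = compute_grm(geno.imputed())
    kept = phio.prune_related(grm, cutoff=config.grm_cutoff)
    if kept.size < n_before:
        geno = geno.subset_individuals(kept)
        phe = np.asarray(phe)[kept]
        cov = cov.iloc[kept].reset_index(drop=True)
    log.append(
        f"relatedness pruning: input={n_before} kept={kept.size} "
        f"removed={n_before - kept.size} cutoff={config.grm_cutoff}"
    )

    m_before = geno.m
    snps = geno.snps.copy()
    if "maf" not in snps.columns:
        snps["maf"] = geno.maf()
    if "info" not in snps.columns:
        snps["info"] = 1.0
    keep_idx = phio.qc_filter(snps, config.maf_min, config.info_min)
    if keep_idx.size < m_before:
        geno = geno.subset_snps(keep_idx)
    log.append(
        f"SNP QC: input={m_before} kept={keep_idx.size} "
        f"removed={m_before - keep_idx.size} "
        f"(maf>={config.maf_min}, info>={config.info_min})"
    )

    gene_map = phio.map_snps_to_genes(geno.snps, genes, config.window_kb)
    log.append(f"gene mapping: {len(gene_map)} genes with >=1 SNP "
               f"(window {config.window_kb} kb)")
    return RunContext(
        config=config,
        genotypes=geno,
        phenotype=np.asarray(phe, dtype=float),
        covariates=cov,
        summary=summary,
        genes=genes,
        pathway_db=db,
        gene_map=gene_map,
        log=log,
    )


def _covariate_array(cov: pd.DataFrame):
    return cov.to_numpy(dtype=float) if cov.shape[1] else None


def run_stage1(ctx: RunContext) -> pd.DataFrame:
    """Test every pathway; append FDR; fixed report schema."""
    cfg = ctx.config
    if cfg.engine == "summary":
        if ctx.summary is None:
            raise ConfigurationError("summary engine requires summary statistics")
        summ = ctx.summary
        snp_table = pd.DataFrame(
            {
                "snp_id": summ["SNP"],
                "chrom": summ["CHR"].astype(str),
                "pos": summ["BP"],
                "maf": summ["MAF"],
                "info": summ["INFO"],
            }
        )
        keep = phio.qc_filter(snp_table, cfg.maf_min, cfg.info_min)
        summ = summ.iloc[keep].reset_index(drop=True)
        ctx.note(f"summary QC: kept {len(keep)} of {len(ctx.summary)} SNPs")
        gmap = phio.map_snps_to_genes(
            pd.DataFrame(
                {
                    "snp_id": summ["SNP"],
                    "chrom": summ["CHR"].astype(str),
                    "pos": summ["BP"],
                }
            ),
            ctx.genes,
            cfg.window_kb,
        )
        gene_tab = pw.gene_min_p(summ, gmap, ctx.genes)
        adjusted = pw.adjust_gene_scores(gene_tab)
        res = pw.magenta_enrichment(
            adjusted,
            ctx.pathway_db,
            cutoff_pct=cfg.magenta_cutoff_pct,
            n_null=cfg.magenta_n_null,
            seed=cfg.seed,
        )
        table = res.copy()
    elif cfg.engine == "genotype":
        rows = []
        cov = _covariate_array(ctx.covariates)
        for k, (name, members) in enumerate(sorted(ctx.pathway_db.pathways.items())):
            sets = {g: ctx.gene_map[g] for g in sorted(members) if g in ctx.gene_map}
            if not sets:
                ctx.note(f"stage1: pathway {name!r} maps to no SNPs; skipped")
                continue
            result = pw.grass_pathway_test(
                ctx.genotypes,
                ctx.phenotype,
                cov,
                sets,
                n_perm=cfg.n_perm_stage1,
                seed=cfg.seed + 1000 + k,
                pathway_name=name,
            )
            rows.append((ctx.pathway_db.source(name), name, result.p))
        table = pd.DataFrame(rows, columns=["database", "pathway", "p"])
        table["p_fdr"] = pw.bh_fdr(table["p"].to_numpy())
        table["eff_gene_size"] = np.nan
        table["exp_count"] = np.nan
        table["obs_count"] = np.nan
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        raise ConfigurationError(f"unknown stage-1 engine {cfg.engine!r}")
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    table = table[STAGE1_COLUMNS]
    n_sig = int((table["p_fdr"] <= cfg.fdr_level).sum())
    ctx.note(f"stage1: {len(table)} pathways tested, {n_sig} significant "
             f"at FDR {cfg.fdr_level}")
    return table


def run_stage2(ctx: RunContext, stage1_table: pd.DataFrame):
    """Regional-heritability fits for the stage-1 significant pathways.

    Pathway-level two-GRM fits with FDR over the significant set, gene-level
    fits for pathways passing, block scans for genes passing, and (when
    enabled) a circular-permutation p for each pathway-level fit.
    """
    cfg = ctx.config
    sig = stage1_table[stage1_table["p_fdr"] <= cfg.fdr_level]["pathway"].tolist()
    cov = _covariate_array(ctx.covariates)
    Z = ctx.genotypes.standardized()
    y = ctx.phenotype
    m = Z.shape[1]
    path_rows, gene_rows, block_frames = [], [], []
    for name in sig:
        try:
            part = reg.partition_by_pathway(
                ctx.genotypes.snps, ctx.gene_map, ctx.pathway_db, name
            )
            res = reg.fit_region_h2(ctx.genotypes, y, cov, part, name=name, Z=Z)
        except Exception as exc:  # per-pathway isolation
            ctx.note(f"stage2: pathway {name!r} failed: {exc}")
            continue
        p_perm = np.nan
        if cfg.run_circular:
            def stat_fn(idx, _Z=Z, _y=y, _cov=cov, _m=m):
                p = reg.Partition(
                    region=np.sort(idx),
                    complement=np.setdiff1d(np.arange(_m), idx),
                )
                return reg.fit_region_h2(None, _y, _cov, p, Z=_Z).h2_region

            nul = reg.circular_null(
                m, part.region, stat_fn, n_perm=cfg.n_perm_circular, seed=cfg.seed
            )
            p_perm = nul.p_perm
        path_rows.append(
            (
                name,
                res.h2_region,
                res.se_region,
                res.h2_comp,
                res.se_comp,
                res.p_lrt,
                p_perm,
                res.n_region_snps,
                res.pct_snp,
                round(res.pct_h2, 2),
                round(res.enrichment_ratio, 2),
            )
        )
    path_table = pd.DataFrame(
        path_rows,
        columns=[
            "pathway",
            "h2_region",
            "se_region",
            "h2_comp",
            "se_comp",
            "p_lrt",
            "p_perm",
            "n_region_snps",
            "pct_snp",
            "pct_h2",
            "enrichment_ratio",
        ],
    )
    if len(path_table):
        path_table["p_lrt_fdr"] = pw.bh_fdr(path_table["p_lrt"].to_numpy())
    else:
        path_table["p_lrt_fdr"] = pd.Series(dtype=float)
    ctx.note(f"stage2: pathway-level fits for {len(path_table)} pathways "
             f"(n_fdr={len(path_table)})")

    passing = path_table[path_table["p_lrt_fdr"] <= cfg.fdr_level]["pathway"]
    for name in passing:
        for g in sorted(ctx.pathway_db.genes(name)):
            idx = ctx.gene_map.get(g)
            if idx is None or len(idx) == 0:
                continue
            part = reg.Partition(
                region=np.asarray(idx), complement=np.setdiff1d(np.arange(m), idx)
            )
            try:
                res = reg.fit_region_h2(ctx.genotypes, y, cov, part, name=g, Z=Z)
            except Exception as exc:
                ctx.note(f"stage2: gene {g!r} failed: {exc}")
                continue
            gene_rows.append(
                (name, g, res.h2_region, res.se_region, res.p_lrt, res.n_region_snps)
            )
    gene_table = pd.DataFrame(
        gene_rows,
        columns=["pathway", "gene_id", "h2", "se", "p_lrt", "n_snps"],
    )

    if cfg.run_scans and len(gene_table):
        pos = ctx.genotypes.snps["pos"].to_numpy()
        for _, row in gene_table[gene_table["p_lrt"] <= 0.05].iterrows():
            g = row["gene_id"]
            blocks = reg.make_blocks(ctx.gene_map[g], cfg.window_n)
            if len(blocks) < 2:
                continue
            scan = reg.scan_gene(ctx.genotypes, y, cov, blocks, Z=Z, positions=pos)
            scan.insert(0, "gene_id", g)
            block_frames.append(scan)
    block_table = (
        pd.concat(block_frames, ignore_index=True)
        if block_frames
        else pd.DataFrame(
            columns=[
                "gene_id", "block", "start_bp", "end_bp", "n_snps",
                "h2", "se", "p", "p_bonf",
            ]
        )
    )
    ctx.note(f"stage2: {len(gene_table)} gene fits, "
             f"{block_table['gene_id'].nunique() if len(block_table) else 0} "
             "genes scanned")
    return path_table, gene_table, block_table


def run_prs(ctx: RunContext, grm=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cutoff x clumping x bin sweep for whole-genome and pathway PRS."""
    cfg = ctx.config
    if ctx.summary is None:
        raise ConfigurationError("PRS stage requires discovery summary statistics")
    if cfg.candidate_pathway is None:
        raise ConfigurationError("candidate_pathway must be set for the PRS stage")
    weights = prsmod.weights_from_summary(ctx.summary)
    path_idx = phio.pathway_snp_indices(
        ctx.pathway_db, ctx.gene_map, cfg.candidate_pathway
    )
    path_snps = set(ctx.genotypes.snps["snp_id"].to_numpy()[path_idx])
    cov = _covariate_array(ctx.covariates)
    y = ctx.phenotype
    if grm is None:
        grm = compute_grm(ctx.genotypes.imputed())
    log_rows, lmm_rows = [], []
    for snp_set, keep in (("whole_genome", None), ("pathway", path_snps)):
        for clumped in cfg.prs_clump_settings:
            keep_ids = keep
            if clumped:
                kept_ids = set(
                    prsmod.clump(
                        ctx.summary,
                        ctx.genotypes,
                        r2_threshold=cfg.prs.clump_r2,
                        window_kb=cfg.prs.clump_window_kb,
                    )
                )
                keep_ids = kept_ids if keep is None else (kept_ids & keep)
            for cutoff in cfg.prs.p_cutoffs:
                scores, n_used = prsmod.compute_prs(
                    ctx.genotypes, weights, p_cutoff=cutoff, keep_snps=keep_ids
                )
                if np.ptp(scores) == 0:
                    ctx.note(
                        f"prs: constant score ({snp_set}, cutoff {cutoff}); skipped"
                    )
                    continue
                ev = prsmod.logistic_eval(y, scores, cov)
                a = prsmod.auc(scores, y)
                log_rows.append(
                    (snp_set, clumped, cutoff, n_used,
                     ev.delta_r2 * 100.0, ev.p_prs, a)
                )
                for B in cfg.prs.bins:
                    if B > len(y) // 2:
                        continue
                    S, _ = prsmod.build_bin_matrix(scores, B)
                    try:
                        fits = prsmod.prs_bin_lmm(y, cov, {"prs_bin": S}, grm=grm)
                    except Exception as exc:
                        ctx.note(f"prs lmm failed ({snp_set}, B={B}): {exc}")
                        continue
                    bin_fit = fits[0]
                    lmm_rows.append(
                        (snp_set, clumped, cutoff, B,
                         bin_fit.proportion, bin_fit.se, bin_fit.p_lrt)
                    )
    log_table = pd.DataFrame(
        log_rows,
        columns=["snp_set", "clumped", "cutoff", "n_snps",
                 "delta_r2_pct", "p", "auc"],
    )
    lmm_table = pd.DataFrame(
        lmm_rows,
        columns=["snp_set", "clumped", "cutoff", "bins", "proportion", "se", "p_lrt"],
    )
    ctx.note(f"prs: {len(log_table)} logistic fits, {len(lmm_table)} LMM fits")
    return log_table, lmm_table


def write_reports(bundle: ReportBundle, outdir) -> list[Path]:
    """Write every populated table as TSV plus the run log; idempotent bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "stage1.tsv": bundle.stage1,
        "stage2_pathway.tsv": bundle.stage2_pathway,
        "stage2_gene.tsv": bundle.stage2_gene,
        "stage2_blocks.tsv": bundle.stage2_blocks,
        "prs_logistic.tsv": bundle.prs_logistic,
        "prs_lmm.tsv": bundle.prs_lmm,
    }
    for fname, tab in tables.items():
        if tab is None:
            continue
        path = outdir / fname
        tab.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(bundle.log) + "\n")
    written.append(log_path)
    return written


def run_all(config: PipelineConfig) -> ReportBundle:
    """simulate/load -> stage 1 -> gated stage 2 -> PRS -> bundle."""
    ctx = prepare_context(config)
    stage1 = run_stage1(ctx)
    path_t, gene_t, block_t = run_stage2(ctx, stage1)
    prs_log, prs_lmm_t = (None, None)
    if ctx.summary is not None and config.candidate_pathway is not None:
        prs_log, prs_lmm_t = run_prs(ctx)
    return ReportBundle(
        stage1=stage1,
        stage2_pathway=path_t,
        stage2_gene=gene_t,
        stage2_blocks=block_t,
        prs_logistic=prs_log,
        prs_lmm=prs_lmm_t,
        log=ctx.log,
    )
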