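"""Synthetic cohorts with blockwise-LD genotypes, a liability-threshold
phenotype enriched in a designated causal pathway, case/control
ascertainment, and an independent discovery sample that yields per-SNP
OR/p summary statistics.

Genotypes come from a latent-Gaussian copula: within each LD block the
latent variables share an exchangeable correlation rho, two independent
haplotype draws are thresholded at the allele-frequency quantile and
summed. Causal effect sizes follow the equal-expected-variance
architecture beta_j ~ N(0, h2 / (m_causal * 2 p_j (1 - p_j))).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import ConfigurationError, ParameterError
from .io import GenotypeMatrix, PathwayDB

__all__ = [
    "SimConfig",
    "Panel",
    "Cohort",
    "make_panel",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_discovery_summary",
    "simulate_all",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic study (target + discovery)."""

    n_target: int = 1000
    n_discovery: int = 4000
    m_snps: int = 2000
    block_size: int = 50
    rho: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 40
    gene_span_snps: int = 20
    pathways: dict[str, int] = field(default_factory=lambda: {"causal": 5, "nullA": 5, "nullB": 5})
    causal_pathway: str = "causal"
    h2_pathway: float = 0.05
    h2_background: float = 0.20
    prevalence_K: float = 0.15
    case_fraction: float = 0.5
    covariate_effects: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ParameterError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must lie within (0, 0.5]")
        if self.h2_pathway + self.h2_background >= 1:
            raise ParameterError("h2_pathway + h2_background must be < 1")
        if not (0 < self.prevalence_K < 1):
            raise ParameterError("prevalence_K must lie in (0, 1)")
        if self.block_size > self.m_snps:
            raise ParameterError("block_size must be <= m_snps")
        if self.block_size < 1 or self.m_snps < 1:
            raise ParameterError("block_size and m_snps must be positive")
        if self.causal_pathway not in self.pathways:
            raise ConfigurationError(
                f"causal pathway {self.causal_pathway!r} not among pathway names"
            )
        if sum(self.pathways.values()) > self.n_genes:
            raise ConfigurationError("pathway gene counts exceed n_genes")


@dataclass
class Panel:
    """SNP panel shared by the target and discovery cohorts."""

    snps: pd.DataFrame  # snp_id, chrom, pos, a1, a2
    freqs: np.ndarray  # allele-1 frequency per SNP
    block_of: np.ndarray  # block index per SNP
    genes: pd.DataFrame  # gene_id, chrom, start, end
    pathway_db: PathwayDB
    gene_snps: dict[str, np.ndarray]  # gene_id -> SNP indices


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    phenotype: np.ndarray  # 0/1
    liability: np.ndarray
    covariates: pd.DataFrame  # age, age2, sex, pc1..pc4
    true_effects: np.ndarray  # per-SNP liability effect sizes
    g_pathway: np.ndarray  # genetic value from causal-pathway SNPs
    g_background: np.ndarray
    threshold: float


_SPACING_BP = 5000


def make_panel(config: SimConfig) -> Panel:
    """Deterministic SNP panel, gene layout and pathway assignment.

    Derived from config.seed only, so the target and discovery cohorts share
    the same panel by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    m = config.m_snps
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    pos = np.arange(m, dtype=int) * _SPACING_BP + 1
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(m)],
            "chrom": "1",
            "pos": pos,
            "a1": "A",
            "a2": "G",
        }
    )
    block_of = np.arange(m) // config.block_size

    stride = max(m // max(config.n_genes, 1), config.gene_span_snps)
    gene_rows = []
    gene_snps: dict[str, np.ndarray] = {}
    for g in range(config.n_genes):
        first = g * stride
        last = min(first + config.gene_span_snps - 1, m - 1)
        if first >= m:
            break
        gid = f"gene{g}"
        gene_rows.append((gid, "1", int(pos[first]), int(pos[last])))
        gene_snps[gid] = np.arange(first, last + 1, dtype=int)
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])

    order = rng.permutation(len(genes))
    cursor = 0
    pathways: dict[str, set[str]] = {}
    for name, size in config.pathways.items():
        chosen = order[cursor : cursor + size]
        pathways[name] = {genes["gene_id"].iloc[i] for i in chosen}
        cursor += size
    db = PathwayDB(pathways=pathways, sources={k: "synthetic" for k in pathways})
    return Panel(
        snps=snps,
        freqs=freqs,
        block_of=block_of,
        genes=genes,
        pathway_db=db,
        gene_snps=gene_snps,
    )


def simulate_genotypes(
    config: SimConfig, n: int, panel: Panel | None = None, stream: int = 0
) -> GenotypeMatrix:
    """Draw n individuals' dosages for the config's SNP panel.

    Within each block of ``block_size`` SNPs, haplotype latents share an
    exchangeable correlation rho; two independent haplotypes are thresholded
    at Phi^-1(freq) and summed, giving dosages in {0, 1, 2} with tunable
    blockwise LD and near-zero between-block correlation.

    ``stream`` separates target (0) and discovery (1) draws under one seed.
    """
    if n < 2:
        raise ParameterError("n must be >= 2")
    if panel is None:
        panel = make_panel(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7, stream]))
    m = config.m_snps
    thr = stats.norm.ppf(panel.freqs)  # latent < thr -> carries allele1
    sr = np.sqrt(config.rho)
    sc = np.sqrt(1 - config.rho)
    X = np.empty((n, m), dtype=float)
    for start in range(0, m, config.block_size):
        stop = min(start + config.block_size, m)
        width = stop - start
        dose = np.zeros((n, width))
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            latent = sr * shared + sc * rng.standard_normal((n, width))
            dose += latent < thr[start:stop]
        X[:, start:stop] = dose
    iid_prefix = "T" if stream == 0 else "D"
    iids = [f"{iid_prefix}{i}" for i in range(n)]
    return GenotypeMatrix(X, iids, panel.snps.copy())


def _draw_effects(
    rng: np.random.Generator, freqs: np.ndarray, causal: np.ndarray, h2: float
) -> np.ndarray:
    beta = np.zeros(freqs.size)
    if h2 <= 0 or causal.size == 0:
        return beta
    var_per = h2 / causal.size
    p = freqs[causal]
    beta[causal] = rng.standard_normal(causal.size) * np.sqrt(
        var_per / (2 * p * (1 - p))
    )
    return beta


def _pathway_snp_set(panel: Panel, pathway: str) -> np.ndarray:
    idx: set[int] = set()
    for g in panel.pathway_db.genes(pathway):
        idx.update(int(i) for i in panel.gene_snps.get(g, ()))
    return np.array(sorted(idx), dtype=int)


def draw_true_effects(config: SimConfig, panel: Panel) -> tuple[np.ndarray, np.ndarray]:
    """(beta_pathway, beta_background) per-SNP liability effects.

    Pathway effects live on every SNP of the causal pathway's genes;
    background effects on all remaining SNPs. Deterministic in config.seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    path_idx = _pathway_snp_set(panel, config.causal_pathway)
    if path_idx.size == 0:
        raise ConfigurationError("causal pathway maps to zero SNPs")
    bg_idx = np.setdiff1d(np.arange(config.m_snps), path_idx)
    beta_path = _draw_effects(rng, panel.freqs, path_idx, config.h2_pathway)
    beta_bg = _draw_effects(rng, panel.freqs, bg_idx, config.h2_background)
    return beta_path, beta_bg


def _genetic_values(X: np.ndarray, freqs: np.ndarray, beta: np.ndarray) -> np.ndarray:
    centered = X - 2 * freqs
    return centered @ beta


def _covariate_table(
    rng: np.random.Generator, X: np.ndarray, n: int
) -> pd.DataFrame:
    age = rng.uniform(18, 65, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    p = X.mean(axis=0) / 2.0
    denom = np.sqrt(2 * p * (1 - p))
    denom[denom == 0] = 1.0
    Z = (X - 2 * p) / denom
    K = Z @ Z.T / Z.shape[1]
    vals, vecs = np.linalg.eigh(K)
    pcs = vecs[:, ::-1][:, :4]
    cov = pd.DataFrame(
        {
            "age": age,
            "age2": age**2,
            "sex": sex,
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
            "pc4": pcs[:, 3],
        }
    )
    return cov


def simulate_phenotype(
    config: SimConfig, panel: Panel | None = None
) -> Cohort:
    """Ascertained case/control target cohort under the liability model.

    liability = G_pathway + G_background + (covariate effects) + e with the
    three variance components h2_pathway, h2_background and the remainder.
    Cases are individuals above the Phi^-1(1 - K) population threshold; the
    returned cohort resamples to ``case_fraction`` cases among ``n_target``
    individuals.
    """
    if panel is None:
        panel = make_panel(config)
    beta_path, beta_bg = draw_true_effects(config, panel)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    K, frac = config.prevalence_K, config.case_fraction
    need_cases = int(round(config.n_target * frac))
    need_ctrls = config.n_target - need_cases
    pool_n = int(
        1.4 * config.n_target * max(frac / K, (1 - frac) / (1 - K))
    ) + 200
    pool = simulate_genotypes(config, pool_n, panel=panel, stream=0)
    X = pool.dosages
    g_path = _genetic_values(X, panel.freqs, beta_path)
    g_bg = _genetic_values(X, panel.freqs, beta_bg)
    var_e = 1.0 - config.h2_pathway - config.h2_background
    e = rng.standard_normal(pool_n) * np.sqrt(var_e)
    liab = g_path + g_bg + e
    if config.covariate_effects:
        cov_pool = _covariate_table(rng, X, pool_n)
        eff = np.zeros(cov_pool.shape[1])
        eff[: len(config.covariate_effects)] = config.covariate_effects
        liab = liab + cov_pool.to_numpy() @ eff
    threshold = float(stats.norm.ppf(1 - K))
    is_case = liab > threshold
    case_idx = np.nonzero(is_case)[0]
    ctrl_idx = np.nonzero(~is_case)[0]
    if case_idx.size < need_cases or ctrl_idx.size < need_ctrls:
        raise ConfigurationError(
            "ascertainment pool too small for requested case_fraction; "
            "lower case_fraction or n_target"
        )
    take = np.concatenate(
        [
            rng.choice(case_idx, size=need_cases, replace=False),
            rng.choice(ctrl_idx, size=need_ctrls, replace=False),
        ]
    )
    take = rng.permutation(take)
    geno = pool.subset_individuals(take)
    # PCs recomputed on the ascertained sample
    covariates = _covariate_table(
        np.random.default_rng(np.random.SeedSequence([config.seed, 37])),
        geno.dosages,
        geno.n,
    )
    return Cohort(
        genotypes=geno,
        phenotype=is_case[take].astype(int),
        liability=liab[take],
        covariates=covariates,
        true_effects=beta_path + beta_bg,
        g_pathway=g_path[take],
        g_background=g_bg[take],
        threshold=threshold,
    )


def _fast_logistic_per_snp(X: np.ndarray, y: np.ndarray, max_iter: int = 25):
    """Vectorized single-SNP logistic regressions (intercept + dosage).

    Newton-Raphson on all SNPs simultaneously with closed-form 2x2 solves.
    Returns (beta, se, p) arrays for the dosage coefficient.
    """
    n, m = X.shape
    b0 = np.full(m, np.log(y.mean() / (1 - y.mean())))
    b1 = np.zeros(m)
    for _ in range(max_iter):
        eta = b0[None, :] + X * b1[None, :]
        mu = expit(eta)
        w = mu * (1 - mu)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (r * X).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * X).sum(axis=0)
        h11 = (w * X * X).sum(axis=0)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        d0 = np.clip(d0, -4, 4)
        d1 = np.clip(d1, -4, 4)
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(), np.abs(d1).max()) < 1e-8:
            break
    eta = b0[None, :] + X * b1[None, :]
    mu = expit(eta)
    w = mu * (1 - mu)
    h00 = w.sum(axis=0)
    h01 = (w * X).sum(axis=0)
    h11 = (w * X * X).sum(axis=0)
    det = h00 * h11 - h01 * h01
    det = np.where(np.abs(det) < 1e-12, 1e-12, det)
    var_b1 = h00 / det
    se = np.sqrt(np.maximum(var_b1, 1e-30))
    z = b1 / se
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return b1, se, p


def simulate_discovery_summary(
    config: SimConfig, panel: Panel | None = None
) -> pd.DataFrame:
    """Independent discovery cohort -> per-SNP summary statistics.

    Draws ``n_discovery`` individuals (disjoint RNG stream from the target
    cohort), assigns case/control status by the same liability model without
    ascertainment, runs a single-SNP logistic regression per SNP, and
    returns a table with columns SNP, CHR, BP, A1, A2, OR, P, INFO, MAF.
    Info scores are Uniform(0.6, 1.0) so downstream QC has work to do.
    """
    if config.n_discovery < 50:
        raise ParameterError("n_discovery < 50: single-SNP logistic fits unstable")
    if panel is None:
        panel = make_panel(config)
    beta_path, beta_bg = draw_true_effects(config, panel)
    beta = beta_path + beta_bg
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53]))
    geno = simulate_genotypes(config, config.n_discovery, panel=panel, stream=1)
    X = geno.dosages
    g = _genetic_values(X, panel.freqs, beta)
    var_e = 1.0 - config.h2_pathway - config.h2_background
    liab = g + rng.standard_normal(config.n_discovery) * np.sqrt(var_e)
    y = (liab > stats.norm.ppf(1 - config.prevalence_K)).astype(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ConfigurationError("discovery sample has a single phenotype class")
    b1, _se, p = _fast_logistic_per_snp(X, y)
    info = rng.uniform(0.6, 1.0, size=config.m_snps)
    maf = np.minimum(panel.freqs, 1 - panel.freqs)
    out = pd.DataFrame(
        {
            "SNP": panel.snps["snp_id"],
            "CHR": panel.snps["chrom"],
            "BP": panel.snps["pos"],
            "A1": panel.snps["a1"],
            "A2": panel.snps["a2"],
            "OR": np.exp(b1),
            "P": p,
            "INFO": info,
            "MAF": maf,
        }
    )
    return out


def simulate_all(config: SimConfig):
    """(panel, target cohort, discovery summary) for one config."""
    panel = make_panel(config)
    cohort = simulate_phenotype(config, panel)
    summary = simulate_discovery_summary(config, panel)
    return panel, cohort, summary
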