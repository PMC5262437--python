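"""Stage-1 pathway association.

Two engines: a genotype-based eigenSNP ridge test with phenotype
permutation (for cohorts with raw genotypes) and a summary-statistic
95th-percentile enrichment test (for GWAS summary data), plus the
multiple-testing utilities the report tables use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import AnalysisError, ParameterError

__all__ = [
    "gene_min_p",
    "adjust_gene_scores",
    "magenta_enrichment",
    "grass_gene_eigensnps",
    "grass_pathway_test",
    "bh_fdr",
    "bonferroni",
]


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def bonferroni(p, n_tests: int):
    """min(1, p * n_tests), elementwise."""
    if n_tests < 1:
        raise ParameterError("n_tests must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * n_tests)


# ---------------------------------------------------------------------------
# summary-statistic engine


def gene_min_p(
    summary: pd.DataFrame,
    gene_map: dict[str, np.ndarray],
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene minimum SNP p-value.

    ``gene_map`` maps gene_id to row indices of ``summary``; ``genes``
    supplies coordinates for the gene length covariate. Genes mapping to
    zero SNPs are dropped; their count is recorded in ``.attrs['n_dropped']``.
    """
    pvals = summary["P"].to_numpy(dtype=float)
    lengths = genes.set_index("gene_id")
    rows = []
    n_dropped = 0
    for gid in genes["gene_id"]:
        idx = gene_map.get(gid)
        if idx is None or len(idx) == 0:
            n_dropped += 1
            continue
        length_kb = (lengths.loc[gid, "end"] - lengths.loc[gid, "start"] + 1) / 1000.0
        rows.append((gid, float(pvals[idx].min()), int(len(idx)), float(length_kb)))
    if not rows:
        raise AnalysisError("every gene maps to zero SNPs")
    out = pd.DataFrame(rows, columns=["gene_id", "min_p", "n_snps", "length_kb"])
    out.attrs["n_dropped"] = n_dropped
    return out


def adjust_gene_scores(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Confounder-corrected gene p-values.

    Regresses -log10(min p) on SNP count and gene length (kb), then maps the
    residuals back to an adjusted p by rank/(n_genes + 1): larger residual
    (more signal than its size predicts) -> smaller adjusted p. With
    degenerate (constant) regressors the raw ranking is used, with a warning.
    """
    n = len(gene_table)
    if n < 30:
        raise ParameterError("adjust_gene_scores needs >= 30 genes for a stable fit")
    score = -np.log10(np.clip(gene_table["min_p"].to_numpy(), 1e-300, 1.0))
    X = np.column_stack(
        [
            np.ones(n),
            gene_table["n_snps"].to_numpy(dtype=float),
            gene_table["length_kb"].to_numpy(dtype=float),
        ]
    )
    if np.ptp(X[:, 1]) == 0 and np.ptp(X[:, 2]) == 0:
        warnings.warn(
            "constant gene size/SNP count: falling back to unadjusted ranks",
            stacklevel=2,
        )
        resid = score
    else:
        coef, *_ = np.linalg.lstsq(X, score, rcond=None)
        resid = score - X @ coef
    # rank 1 = largest residual; stable ties
    order = np.argsort(-resid, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    out = gene_table.copy()
    out["residual"] = resid
    out["adj_p"] = rank / (n + 1)
    return out


def magenta_enrichment(
    adjusted: pd.DataFrame,
    pathway_db,
    cutoff_pct: float = 95.0,
    n_null: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile-cutoff enrichment over adjusted gene p-values.

    A pathway's observed count is the number of its genes with adjusted p
    below the (100 - cutoff_pct)th percentile of all genes' adjusted p; the
    expected count is effective_size * (1 - cutoff_pct / 100). The nominal p
    is (r + 1) / (n_null + 1) with r the number of random same-size gene sets
    whose count is >= observed. Pathways mapping to zero table genes are
    skipped with a warning.
    """
    if n_null < 1000:
        raise ParameterError("n_null must be >= 1000")
    rng = np.random.default_rng(seed)
    adj = adjusted["adj_p"].to_numpy()
    gene_ids = adjusted["gene_id"].to_numpy()
    id_to_row = {g: i for i, g in enumerate(gene_ids)}
    thr = np.percentile(adj, 100.0 - cutoff_pct)
    hit = adj < thr
    n_genes = adj.size
    rows = []
    for name, members in pathway_db:
        rows_in = np.array(
            sorted(id_to_row[g] for g in members if g in id_to_row), dtype=int
        )
        eff = rows_in.size
        if eff == 0:
            warnings.warn(f"pathway {name!r} maps to no scored gene; skipped",
                          stacklevel=2)
            continue
        observed = int(hit[rows_in].sum())
        expected = eff * (1 - cutoff_pct / 100.0)
        # random same-size gene sets: the eff smallest of n_genes uniform keys
        keys = rng.random((n_null, n_genes))
        null_idx = np.argpartition(keys, eff - 1, axis=1)[:, :eff]
        null_counts = hit[null_idx].sum(axis=1)
        r = int((null_counts >= observed).sum())
        p = (r + 1) / (n_null + 1)
        rows.append(
            (
                name,
                pathway_db.source(name),
                p,
                eff,
                round(expected, 1),
                observed,
            )
        )
    if not rows:
        raise AnalysisError("no pathway could be scored")
    out = pd.DataFrame(
        rows,
        columns=["pathway", "database", "p", "eff_gene_size", "exp_count", "obs_count"],
    )
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# genotype engine


def grass_gene_eigensnps(
    genotypes, gene_snps, var_explained: float = 0.95
) -> np.ndarray:
    """EigenSNPs of one gene: principal components of its standardized
    genotypes retaining at least ``var_explained`` of the variance.

    ``genotypes`` may be a GenotypeMatrix or an already-standardized n x m
    array. Raises AnalysisError when every SNP in the gene is monomorphic.
    """
    if hasattr(genotypes, "dosages"):
        X = genotypes.imputed().dosages[:, np.asarray(gene_snps, dtype=int)]
        sd = X.std(axis=0)
        poly = sd > 0
        if not poly.any():
            raise AnalysisError("all SNPs in gene are monomorphic")
        Z = (X[:, poly] - X[:, poly].mean(axis=0)) / sd[poly]
    else:
        Z = np.asarray(genotypes, dtype=float)[:, np.asarray(gene_snps, dtype=int)]
        sd = Z.std(axis=0)
        poly = sd > 0
        if not poly.any():
            raise AnalysisError("all SNPs in gene are monomorphic")
        Z = Z[:, poly]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise AnalysisError("gene genotype block has zero variance")
    cum = np.cumsum(var) / total
    k = int(np.searchsorted(cum, var_explained - 1e-12) + 1)
    k = min(k, Z.shape[1])
    comps = U[:, :k] * s[:k]
    return comps


def _ridge_logistic_deviance(
    X: np.ndarray, y: np.ndarray, penalty: np.ndarray, max_iter: int = 50
) -> float:
    """Deviance (-2 loglik, unpenalized) at the ridge-penalized MLE.

    ``penalty`` is the per-coefficient L2 weight (0 for unpenalized terms).
    """
    n, p = X.shape
    b = np.zeros(p)
    pen = np.asarray(penalty, dtype=float)
    for _ in range(max_iter):
        eta = X @ b
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = X.T @ (y - mu) - pen * b
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += pen + 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        b += step
        if np.abs(step).max() < 1e-8:
            break
    eta = X @ b
    ll = float(y @ eta - np.logaddexp(0, eta).sum())
    return -2.0 * ll


def _deviance_reduction(
    E: np.ndarray, C: np.ndarray, y: np.ndarray, lam: float
) -> float:
    pen_cov = np.zeros(C.shape[1])
    dev_cov = _ridge_logistic_deviance(C, y, pen_cov)
    Xf = np.column_stack([C, E])
    pen_full = np.concatenate([pen_cov, np.full(E.shape[1], lam)])
    dev_full = _ridge_logistic_deviance(Xf, y, pen_full)
    return dev_cov - dev_full


def _cv_penalty(
    E: np.ndarray, C: np.ndarray, y: np.ndarray, grid, n_folds: int, rng
) -> float:
    n = y.size
    folds = rng.permutation(n) % n_folds
    Xf = np.column_stack([C, E])
    best_lam, best_dev = grid[0], np.inf
    for lam in grid:
        pen = np.concatenate([np.zeros(C.shape[1]), np.full(E.shape[1], lam)])
        dev = 0.0
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            if y[tr].min() == y[tr].max():
                dev = np.inf
                break
            b = _ridge_logistic_coef(Xf[tr], y[tr], pen)
            eta = Xf[te] @ b
            dev += -2.0 * float(y[te] @ eta - np.logaddexp(0, eta).sum())
        if dev < best_dev:
            best_dev, best_lam = dev, lam
    return best_lam


def _ridge_logistic_coef(X, y, penalty, max_iter: int = 50) -> np.ndarray:
    b = np.zeros(X.shape[1])
    pen = np.asarray(penalty, dtype=float)
    for _ in range(max_iter):
        mu = expit(X @ b)
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = X.T @ (y - mu) - pen * b
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += pen + 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        b += step
        if np.abs(step).max() < 1e-8:
            break
    return b


@dataclass
class GrassResult:
    pathway: str
    statistic: float
    p: float
    n_perm: int
    n_eigensnps: int
    penalty: float


def grass_pathway_test(
    genotypes,
    phenotype,
    covariates,
    gene_snp_sets: dict[str, np.ndarray],
    n_perm: int = 999,
    seed: int = 0,
    var_explained: float = 0.95,
    penalty: float | None = None,
    pathway_name: str = "",
) -> GrassResult:
    """Pathway association from raw genotypes by phenotype permutation.

    Statistic: deviance reduction of a ridge-penalized logistic regression
    (all of the pathway's gene eigenSNPs + covariates) over the
    covariates-only model. The ridge penalty is chosen once by 5-fold
    cross-validated deviance on the unpermuted data and held fixed across
    permutations, keeping the permutation test valid. p = (r + 1)/(B + 1).
    """
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99; 999+ recommended for reporting")
    return _grass_test_impl(
        genotypes, phenotype, covariates, gene_snp_sets, n_perm, seed,
        var_explained, penalty, pathway_name,
    )


def _grass_test_impl(
    genotypes,
    phenotype,
    covariates,
    gene_snp_sets,
    n_perm,
    seed,
    var_explained=0.95,
    penalty=None,
    pathway_name="",
) -> GrassResult:
    y = np.asarray(phenotype, dtype=float).ravel()
    if y.min() == y.max():
        raise AnalysisError("phenotype has a single class")
    blocks = []
    for gid, idx in gene_snp_sets.items():
        if len(idx) == 0:
            continue
        try:
            blocks.append(grass_gene_eigensnps(genotypes, idx, var_explained))
        except AnalysisError:
            warnings.warn(f"gene {gid!r} dropped (monomorphic)", stacklevel=2)
    if not blocks:
        raise AnalysisError("pathway maps to zero usable SNPs")
    E = np.column_stack(blocks)
    n = y.size
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.atleast_2d(np.asarray(covariates, float))])
    rng = np.random.default_rng(seed)
    if penalty is None:
        penalty = _cv_penalty(E, C, y, grid=(0.1, 1.0, 10.0, 100.0), n_folds=5, rng=rng)
    observed = _deviance_reduction(E, C, y, penalty)
    r = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        if _deviance_reduction(E, C, yp, penalty) >= observed:
            r += 1
    p = (r + 1) / (n_perm + 1)
    return GrassResult(
        pathway=pathway_name,
        statistic=float(observed),
        p=float(p),
        n_perm=n_perm,
        n_eigensnps=E.shape[1],
        penalty=float(penalty),
    )
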