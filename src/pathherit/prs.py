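"""Polygenic risk scoring and evaluation.

Scores are risk-allele dosages weighted by discovery log odds ratios under
a discovery p-value cutoff, optionally after greedy LD clumping. Fixed-
effect evaluation uses logistic regression with Nagelkerke's delta-R2 and
Mann-Whitney AUC; the random-effect route bins individuals by PRS rank,
builds a same-bin indicator covariance, and fits it (optionally alongside
a GRM) by REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import AnalysisError, ParameterError
from .vc import lrt_p, reml_fit

__all__ = [
    "PRSConfig",
    "weights_from_summary",
    "clump",
    "compute_prs",
    "logistic_eval",
    "auc",
    "build_bin_matrix",
    "prs_bin_lmm",
]


@dataclass
class PRSConfig:
    p_cutoffs: tuple[float, ...] = (0.2, 0.5, 1.0)
    clumping: bool = False
    clump_r2: float = 0.25
    clump_window_kb: float = 250.0
    bins: tuple[int, ...] = (10, 20, 50, 100, 200)

    def __post_init__(self) -> None:
        if any(not (0 < c <= 1) for c in self.p_cutoffs):
            raise ParameterError("p cutoffs must lie in (0, 1]")


def weights_from_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """PRS weight table (SNP, A1, weight, P) from discovery summary stats.

    weight = log(OR); a BETA column is used directly when OR is absent.
    """
    if "OR" in summary.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.log(summary["OR"].to_numpy(dtype=float))
    elif "BETA" in summary.columns:
        w = summary["BETA"].to_numpy(dtype=float)
    else:
        raise ParameterError("summary must carry an OR or BETA column")
    if not np.isfinite(w).all():
        raise ParameterError("non-finite PRS weights")
    return pd.DataFrame(
        {
            "SNP": summary["SNP"].to_numpy(),
            "A1": summary["A1"].to_numpy(),
            "weight": w,
            "P": summary["P"].to_numpy(dtype=float),
        }
    )


def clump(
    summary: pd.DataFrame,
    genotypes,
    r2_threshold: float = 0.25,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy LD clumping against target-genotype correlations.

    Sort by p ascending; keep the best unclaimed SNP and remove every SNP
    within ``window_kb`` whose r2 with it exceeds the threshold; repeat.
    Returns the kept SNP IDs (summary order among kept preserved by p rank).
    """
    snp_col = {s: i for i, s in enumerate(genotypes.snps["snp_id"])}
    rows = summary[summary["SNP"].isin(snp_col)].copy()
    rows = rows.sort_values("P", kind="stable")
    cols = np.array([snp_col[s] for s in rows["SNP"]], dtype=int)
    pos = genotypes.snps["pos"].to_numpy()[cols]
    chrom = genotypes.snps["chrom"].astype(str).to_numpy()[cols]
    X = genotypes.imputed().dosages[:, cols]
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    n = Z.shape[0]
    window = window_kb * 1000.0
    alive = np.ones(len(cols), dtype=bool)
    kept: list[str] = []
    snp_ids = rows["SNP"].to_numpy()
    for i in range(len(cols)):
        if not alive[i]:
            continue
        kept.append(str(snp_ids[i]))
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        if near.any():
            r = (Z[:, near].T @ Z[:, i]) / n
            drop = np.nonzero(near)[0][r**2 > r2_threshold]
            alive[drop] = False
    return kept


def compute_prs(
    genotypes, weights: pd.DataFrame, p_cutoff: float = 1.0, keep_snps=None
):
    """Per-individual weighted risk-allele score.

    score_i = sum over SNPs with discovery p <= cutoff of
    dosage(effect allele)_is * weight_s. Dosages are flipped (2 - x) where
    the weight's effect allele is the panel's allele2; SNPs whose effect
    allele matches neither panel allele are dropped and counted.

    Returns (scores, n_snps_used).
    """
    sel = weights[weights["P"] <= p_cutoff]
    if keep_snps is not None:
        keep = set(keep_snps)
        sel = sel[sel["SNP"].isin(keep)]
    snps = genotypes.snps
    col_of = {s: i for i, s in enumerate(snps["snp_id"])}
    a1 = snps["a1"].to_numpy()
    a2 = snps["a2"].to_numpy()
    X = genotypes.imputed().dosages
    scores = np.zeros(genotypes.n)
    used = 0
    dropped = 0
    for snp, allele, w in zip(sel["SNP"], sel["A1"], sel["weight"]):
        j = col_of.get(snp)
        if j is None:
            dropped += 1
            continue
        if allele == a1[j]:
            dose = X[:, j]
        elif allele == a2[j]:
            dose = 2.0 - X[:, j]
        else:
            dropped += 1
            continue
        scores += dose * w
        used += 1
    if dropped:
        warnings.warn(f"{dropped} SNPs dropped (absent or allele mismatch)",
                      stacklevel=2)
    return scores, used


def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Nagelkerke pseudo-R2 of a fitted model against the intercept-only fit."""
    cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_null / n)
    return float(cs / max_cs)


@dataclass
class LogisticEval:
    delta_r2: float
    r2_full: float
    r2_cov: float
    p_prs: float
    beta_prs: float
    penalized: bool


def logistic_eval(y, prs, covariates) -> LogisticEval:
    """Fixed-effect PRS evaluation by logistic regression.

    delta Nagelkerke R2 = R2(covariates + PRS) - R2(covariates only), both
    against the intercept-only likelihood; the association p is the Wald p
    of the PRS coefficient. On (quasi-)separation a lightly ridge-penalized
    refit is used and flagged.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.min() == y.max():
        raise AnalysisError("phenotype has a single class")
    n = y.size
    prs = np.asarray(prs, dtype=float).ravel()
    if np.ptp(prs) == 0:  # no information: delta-R2 is 0 by definition
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll0 = sm.Logit(y, np.ones((n, 1))).fit(disp=0).llf
        if covariates is None:
            llc = ll0
        else:
            C = np.column_stack(
                [np.ones(n), np.atleast_2d(np.asarray(covariates, float))]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                llc = sm.Logit(y, C).fit(disp=0).llf
        r2_cov = nagelkerke_r2(llc, ll0, n)
        return LogisticEval(
            delta_r2=0.0, r2_full=r2_cov, r2_cov=r2_cov,
            p_prs=1.0, beta_prs=0.0, penalized=False,
        )
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.atleast_2d(np.asarray(covariates, float))])
    Xf = np.column_stack([C, prs])
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m_null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
            m_cov = sm.Logit(y, C).fit(disp=0)
            m_full = sm.Logit(y, Xf).fit(disp=0)
        ll0, llc, llf = m_null.llf, m_cov.llf, m_full.llf
        beta = float(m_full.params[-1])
        p_prs = float(m_full.pvalues[-1])
        if not np.isfinite([ll0, llc, llf, beta, p_prs]).all():
            raise np.linalg.LinAlgError
    except Exception:  # separation and friends
        from .pathway import _ridge_logistic_coef

        penalized = True
        lam = 1e-3
        def _fit(X):
            pen = np.full(X.shape[1], lam)
            b = _ridge_logistic_coef(X, y, pen)
            eta = X @ b
            return float(y @ eta - np.logaddexp(0, eta).sum()), b
        ll0, _ = _fit(np.ones((n, 1)))
        llc, _ = _fit(C)
        llf, bf = _fit(Xf)
        beta = float(bf[-1])
        stat = max(0.0, 2.0 * (llf - llc))
        p_prs = float(stats.chi2.sf(stat, df=1))
    r2_full = nagelkerke_r2(llf, ll0, n)
    r2_cov = nagelkerke_r2(llc, ll0, n)
    return LogisticEval(
        delta_r2=r2_full - r2_cov,
        r2_full=r2_full,
        r2_cov=r2_cov,
        p_prs=p_prs,
        beta_prs=beta,
        penalized=penalized,
    )


def auc(prs, y) -> float:
    """Mann-Whitney AUC: Pr(random case outscores random control), ties 1/2."""
    y = np.asarray(y).ravel().astype(int)
    prs = np.asarray(prs, dtype=float).ravel()
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise AnalysisError("AUC requires both classes")
    ranks = stats.rankdata(prs)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def build_bin_matrix(prs, B: int):
    """Same-PRS-bin indicator covariance.

    Individuals are ranked by PRS (stable ties) and cut into B equal-count
    quantile bins; S_ij = 1 if i and j share a bin. Returns (S, bins).
    """
    prs = np.asarray(prs, dtype=float).ravel()
    n = prs.size
    if B < 2:
        raise ParameterError("B must be >= 2 (B = 1 is confounded with the intercept)")
    if B > n // 2:
        raise ParameterError("B must be <= n/2")
    order = np.argsort(prs, kind="stable")
    bins = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(order, B)):
        bins[chunk] = b
    S = (bins[:, None] == bins[None, :]).astype(float)
    return S, bins


@dataclass
class BinLmmResult:
    name: str
    proportion: float
    se: float
    p_lrt: float
    lrt_stat: float
    loglik_full: float
    converged: bool


def prs_bin_lmm(y, covariates, bin_matrices: dict, grm=None) -> list[BinLmmResult]:
    """REML fit of PRS-bin covariance(s), optionally joint with a GRM.

    ``bin_matrices`` maps a label to an (n, n) same-bin indicator matrix.
    Each bin matrix gets a p_lrt by refitting without it (boundary mixture).
    The GRM, when supplied, is reported without its own LRT.
    """
    names = list(bin_matrices.keys())
    mats = [np.asarray(bin_matrices[k], dtype=float) for k in names]
    all_names = list(names)
    if grm is not None:
        mats.append(grm.values if hasattr(grm, "values") else np.asarray(grm))
        all_names.append("grm")
    full = reml_fit(y, covariates, mats, names=all_names)
    out = []
    for k, name in enumerate(names):
        reduced_mats = [m for j, m in enumerate(mats) if j != k]
        reduced_names = [nm for j, nm in enumerate(all_names) if j != k]
        if reduced_mats:
            null = reml_fit(y, covariates, reduced_mats, names=reduced_names)
            null_ll = null.loglik
        else:
            null_ll = _covariates_only_loglik(y, covariates)
        stat, p = lrt_p(full.loglik, null_ll)
        out.append(
            BinLmmResult(
                name=name,
                proportion=full.proportion(name),
                se=full.se_of(name) / max(float(np.sum(full.variances)), 1e-300),
                p_lrt=p,
                lrt_stat=stat,
                loglik_full=full.loglik,
                converged=full.converged,
            )
        )
    if grm is not None:
        out.append(
            BinLmmResult(
                name="grm",
                proportion=full.proportion("grm"),
                se=full.se_of("grm") / max(float(np.sum(full.variances)), 1e-300),
                p_lrt=np.nan,
                lrt_stat=np.nan,
                loglik_full=full.loglik,
                converged=full.converged,
            )
        )
    return out


def _covariates_only_loglik(y, covariates) -> float:
    """Restricted log-likelihood of the residual-only linear model."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if covariates is None:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), np.atleast_2d(np.asarray(covariates, float))])
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, abs(r[0, 0]))
    X = X[:, keep]
    p = X.shape[1]
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    _, logdet_xx = np.linalg.slogdet(X.T @ X)
    # same constant convention as vc.reml_fit: -0.5(log|V| + log|X'V^-1 X|
    # + y'Py + (n-p) log 2pi) evaluated at V = s2 I
    return -0.5 * (
        (n - p) * np.log(s2) + logdet_xx + (n - p) + (n - p) * np.log(2 * np.pi)
    )
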