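"""GREML variance-component machinery.

Genomic relationship matrices (GRMs), multi-matrix average-information
REML with an EM warm-up, the boundary-corrected likelihood-ratio test for
a single variance component, and the observed-to-liability scale
transformation for binary traits analysed as 0/1 with a linear mixed
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .errors import IdentifiabilityError, NumericalError, ParameterError

__all__ = [
    "GRM",
    "VCFit",
    "compute_grm",
    "reml_fit",
    "lrt_p",
    "observed_to_liability",
]


@dataclass
class GRM:
    """Genomic relationship matrix with the individual IDs it is aligned to.

    Attributes
    ----------
    values : (n, n) ndarray
        Symmetric relationship matrix.
    ids : list of str
        Individual IDs, row/column order of ``values``.
    n_snps : int
        Number of SNPs that entered the estimator.
    """

    values: np.ndarray
    ids: list[str]
    n_snps: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("GRM must be a square matrix")
        if len(self.ids) != v.shape[0]:
            raise ParameterError("GRM id count does not match matrix order")
        self.values = v


@dataclass
class VCFit:
    """Result of a multi-matrix REML fit.

    ``variances[k]`` is the estimate for component ``names[k]``; the last
    component is always the residual. ``proportions`` are each component's
    share of the total fitted phenotypic variance (residual included in the
    denominator, excluded from the reported vector's tail only by name).
    """

    names: list[str]
    variances: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n: int
    n_fixed: int
    loglik_path: list = field(default_factory=list, repr=False)
    proportions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = float(np.sum(self.variances))
        if total <= 0:
            total = np.nan
        self.proportions = self.variances / total

    def proportion(self, name: str) -> float:
        return float(self.proportions[self.names.index(name)])

    def variance(self, name: str) -> float:
        return float(self.variances[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])


def compute_grm(genotypes, snp_subset=None) -> GRM:
    """GCTA-style GRM from dosages.

    A_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    with p_i the sample allele frequency of the effect allele. Monomorphic
    SNPs are excluded from m. Missing dosages must already be mean-imputed
    (see GenotypeMatrix.imputed).

    Parameters
    ----------
    genotypes : GenotypeMatrix
    snp_subset : sequence of int, optional
        Column indices to use; defaults to all SNPs.
    """
    X = genotypes.dosages
    if snp_subset is not None:
        idx = np.asarray(list(snp_subset), dtype=int)
        X = X[:, idx]
    if np.isnan(X).any():
        X = _mean_impute(X)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ParameterError("SNP subset is entirely monomorphic")
    Xp = X[:, poly]
    pp = p[poly]
    Z = (Xp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    m = Z.shape[1]
    A = (Z @ Z.T) / m
    A = (A + A.T) / 2.0
    return GRM(values=A, ids=list(genotypes.iids), n_snps=m)


def grm_from_standardized(Z: np.ndarray, ids: list[str]) -> GRM:
    """GRM directly from an already-standardized genotype block Z (n x m)."""
    m = Z.shape[1]
    A = (Z @ Z.T) / m
    return GRM(values=(A + A.T) / 2.0, ids=list(ids), n_snps=m)


def _mean_impute(X: np.ndarray) -> np.ndarray:
    X = X.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    return X


def _check_identifiable(mats: list[np.ndarray], n: int) -> None:
    eye = np.eye(n)
    flat_eye = eye.ravel()
    flats = []
    for k, A in enumerate(mats):
        f = A.ravel()
        nf = np.linalg.norm(f)
        if nf == 0:
            raise IdentifiabilityError(f"matrix {k} is zero")
        cos = float(f @ flat_eye) / (nf * np.sqrt(n))
        if cos > 1 - 1e-10 and np.allclose(A, A[0, 0] * eye, atol=1e-10):
            raise IdentifiabilityError(
                f"matrix {k} is proportional to the identity; its variance "
                "component is confounded with the residual"
            )
        flats.append(f / nf)
    for i in range(len(flats)):
        for j in range(i + 1, len(flats)):
            if abs(float(flats[i] @ flats[j])) > 1 - 1e-10:
                raise IdentifiabilityError(f"matrices {i} and {j} are proportional")


def _restricted_ll(sigma, all_mats, X, y, n, p_fix):
    V = np.zeros((n, n))
    for s2, A in zip(sigma, all_mats):
        V += s2 * A
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    ViX = cho_solve((c, low), X)
    Viy = cho_solve((c, low), y)
    XtViX = X.T @ ViX
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    yPy = float(y @ Viy - (X.T @ Viy) @ beta)
    return -0.5 * (logdet_v + logdet_x + yPy + (n - p_fix) * np.log(2 * np.pi))


def reml_fit(
    y,
    covariates,
    matrices,
    names=None,
    max_iter: int = 100,
    tol: float = 1e-4,
    em_steps: int = 3,
    start=None,
) -> VCFit:
    """Average-information REML for V = sum_k sigma2_k A_k + sigma2_e I.

    The first ``em_steps`` iterations use EM updates (guaranteed not to
    decrease the restricted likelihood), after which AI updates take over.
    Negative component estimates are truncated at zero, GCTA-style, so the
    LRT boundary mixture applies downstream. Standard errors come from the
    inverse AI matrix at the solution.

    Parameters
    ----------
    y : (n,) array
        Phenotype (binary traits passed as 0/1 on the observed scale).
    covariates : (n, c) array or None
        Fixed-effect covariates; an intercept column is always added.
    matrices : sequence of GRM or (n, n) ndarray
        Relationship matrices, one per genetic variance component. The
        residual identity component is implicit and must not be supplied.
    names : sequence of str, optional
        Component labels; defaults to g1..gK. The residual is named "e".

    Returns
    -------
    VCFit

    Raises
    ------
    IdentifiabilityError
        If a supplied matrix is (proportional to) the identity or two
        matrices are proportional to each other.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 50:
        raise ParameterError("reml_fit requires n >= 50")
    mats = []
    for A in matrices:
        if isinstance(A, GRM):
            A = A.values
        A = np.asarray(A, dtype=float)
        if A.shape != (n, n):
            raise ParameterError("relationship matrix shape does not match y")
        mats.append(A)
    if not mats:
        raise ParameterError("at least one relationship matrix is required")
    _check_identifiable(mats, n)
    K = len(mats)
    if names is None:
        names = [f"g{k + 1}" for k in range(K)]
    names = list(names) + ["e"]

    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([np.ones(n), C])
    # drop linearly dependent fixed-effect columns
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, abs(r[0, 0]))
    if not keep.all():
        X = X[:, keep]
    p_fix = X.shape[1]

    vp = float(np.var(y, ddof=1))
    if start is not None:
        sigma = np.asarray(start, dtype=float).copy()
        if sigma.size != K + 1:
            raise ParameterError("start must supply K + 1 variance components")
        sigma = np.maximum(sigma, 1e-6 * vp)
    else:
        sigma = np.full(K + 1, vp / (K + 1))
    all_mats = mats + [np.eye(n)]

    loglik = -np.inf
    loglik_path: list[float] = []
    converged = False
    floor = 1e-8 * vp
    AI = np.eye(K + 1)
    it = 0

    def _clamp(s):
        s = s.copy()
        s[:-1] = np.maximum(s[:-1], 0.0)
        if s[-1] <= 0:
            s[-1] = floor
        return s

    for it in range(1, max_iter + 1):
        V = np.zeros((n, n))
        for s2, A in zip(sigma, all_mats):
            V += s2 * A
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            sigma = np.maximum(sigma, 1e-4 * vp)
            continue
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vinv = cho_solve((c, low), np.eye(n))
        ViX = Vinv @ X
        XtViX = X.T @ ViX
        sign, logdet_x = np.linalg.slogdet(XtViX)
        XtViX_inv = np.linalg.inv(XtViX)
        P = Vinv - ViX @ XtViX_inv @ ViX.T
        Py = P @ y
        new_loglik = -0.5 * (
            logdet_v + logdet_x + float(y @ Py) + (n - p_fix) * np.log(2 * np.pi)
        )
        loglik_path.append(new_loglik)

        if it > em_steps + 1 and abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

        APy = [A @ Py for A in all_mats]
        trPA = np.array([float(np.sum(P * A)) for A in all_mats])
        yPAPy = np.array([float(Py @ a) for a in APy])
        dL = -0.5 * (trPA - yPAPy)
        AI = np.empty((K + 1, K + 1))
        PAPy = [P @ a for a in APy]
        for i_ in range(K + 1):
            for j_ in range(i_, K + 1):
                AI[i_, j_] = AI[j_, i_] = 0.5 * float(APy[i_] @ PAPy[j_])

        em_step = (sigma**2) * (yPAPy - trPA) / n
        if it <= em_steps:
            step = em_step
        else:
            try:
                step = np.linalg.solve(AI, dL)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(AI, dL, rcond=None)[0]
        # step-halving keeps the restricted likelihood non-decreasing;
        # falls back to the (ascent-guaranteed) EM direction if needed
        accepted = None
        for trial in [step * 0.5**t for t in range(6)] + [em_step]:
            cand = _clamp(sigma + trial)
            if _restricted_ll(cand, all_mats, X, y, n, p_fix) >= loglik - 1e-9:
                accepted = cand
                break
        sigma = accepted if accepted is not None else _clamp(sigma + em_step)

    try:
        cov = np.linalg.inv(AI)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(K + 1, np.nan)

    return VCFit(
        names=names,
        variances=sigma.copy(),
        se=se,
        loglik=float(loglik),
        converged=converged,
        n_iter=it,
        n=n,
        n_fixed=p_fix,
        loglik_path=loglik_path,
    )


def lrt_p(loglik_full: float, loglik_null: float, tol: float = 1e-6):
    """Boundary-corrected LRT for one nonnegative variance component.

    The null distribution is the 50:50 mixture of a point mass at zero and
    chi-square with 1 df, so p = 0.5 when the statistic is 0 and
    0.5 * Pr(chi2_1 >= stat) otherwise.

    Returns
    -------
    (statistic, p) tuple
    """
    if loglik_full < loglik_null - tol:
        raise NumericalError(
            f"full-model log-likelihood {loglik_full} below null {loglik_null}"
        )
    stat = max(0.0, 2.0 * (loglik_full - loglik_null))
    if stat == 0.0:
        return 0.0, 0.5
    return stat, 0.5 * float(stats.chi2.sf(stat, df=1))


def observed_to_liability(h2_obs: float, K: float, P: float) -> float:
    """Transform an observed-scale (0/1 LMM) h2 to the liability scale.

    h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) z^2) with z the standard
    normal density at the liability threshold Phi^-1(1-K); K is population
    prevalence and P the sample case proportion.
    """
    if not (0 < K < 1) or not (0 < P < 1):
        raise ParameterError("K and P must lie in (0, 1)")
    if h2_obs < 0:
        import warnings

        warnings.warn("negative h2_obs passed through as 0", stacklevel=2)
        return 0.0
    z = stats.norm.pdf(stats.norm.ppf(1 - K))
    return h2_obs * K**2 * (1 - K) ** 2 / (P * (1 - P) * z**2)
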