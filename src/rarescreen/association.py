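"""Per-cohort gene-burden association testing and contingency statistics.

The test regresses the binary phenotype on the gene's 0/1 carrier indicator
plus demographic covariates (age, sex, age*sex, age^2, sex*age^2) using
Firth-penalized logistic regression. The Jeffreys-prior penalty keeps
estimates finite under the extreme case-control imbalance and complete
separation that rare carrier indicators routinely produce. P-values come
from the penalized likelihood-ratio statistic by default (Wald optional);
the null fit constrains the burden coefficient to zero while keeping the
full design in the penalty, so the two likelihoods share one penalty.

Alongside the regression, each gene-phenotype pair gets its 2x2 table
(carrier cases a, carrier controls b, non-carrier cases c, non-carrier
controls d), the table odds ratio with Haldane-Anscombe correction, and the
positive predictive value a/(a+b) in the all-ages and 60+ strata. PPV is the
empirical penetrance estimate the screening stage thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .config import ThresholdConfig

__all__ = [
    "CovariateSet",
    "CohortAssocResult",
    "FirthFit",
    "ConstantPhenotypeError",
    "build_covariates",
    "firth_logistic",
    "fit_burden_test",
    "contingency_stats",
    "compute_ppv",
    "associate_pair",
]


class ConstantPhenotypeError(ValueError):
    """Raised when the phenotype vector has no variation."""


@dataclass
class CovariateSet:
    """Assembled covariate design (no intercept, no burden column).

    Derived interaction terms are always recomputed from age and sex here,
    never ingested. Continuous columns are standardized internally at fit
    time; coefficients for the burden indicator are unaffected.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            raise ValueError("covariates contain missing values")


def build_covariates(
    age: Sequence[float],
    sex: Optional[Sequence[int]] = None,
    extra: Optional[pd.DataFrame] = None,
) -> CovariateSet:
    """Standard covariate formula: age, sex, age*sex, age^2, sex*age^2.

    ``sex`` is 0/1; pass ``None`` for sex-restricted analyses (the sex
    covariate and its interactions are then dropped). ``extra`` columns
    (e.g. pipeline version indicators, ancestry components) are appended.
    """
    age = np.asarray(age, dtype=float)
    cols = {"age": age, "age_sq": age**2}
    if sex is not None:
        sex = np.asarray(sex, dtype=float)
        cols["sex"] = sex
        cols["age_sex"] = age * sex
        cols["sex_age_sq"] = sex * age**2
    frame = pd.DataFrame(cols)
    if extra is not None:
        frame = pd.concat([frame, extra.reset_index(drop=True)], axis=1)
    return CovariateSet(frame=frame)


@dataclass
class FirthFit:
    beta: np.ndarray
    se: np.ndarray
    pen_loglik: float
    converged: bool
    n_iter: int


def _pen_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    eta = X @ beta
    mu = special.expit(eta)
    eps = 1e-12
    ll = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf, mu, info
    return ll + 0.5 * logdet, mu, info


def firth_logistic(
    X: np.ndarray,
    y: np.ndarray,
    fixed_zero: Optional[Sequence[int]] = None,
    start: Optional[np.ndarray] = None,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> FirthFit:
    """Maximize the Jeffreys-penalized logistic likelihood.

    ``fixed_zero`` lists coefficient indices constrained to zero (profile
    fit); the penalty always uses the full design so constrained and free
    fits are comparable in a likelihood-ratio test.
    """
    n, p = X.shape
    free = np.ones(p, dtype=bool)
    if fixed_zero is not None:
        free[list(fixed_zero)] = False
    beta = np.zeros(p) if start is None else np.array(start, dtype=float)
    beta[~free] = 0.0

    pll, mu, info = _pen_loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * (1.0 - mu)
        # hat-diagonal for the modified score, from the full information
        try:
            cf = linalg.cho_factor(info, lower=True, check_finite=False)
        except linalg.LinAlgError:
            info = info + 1e-8 * np.eye(p)
            cf = linalg.cho_factor(info, lower=True, check_finite=False)
        V = linalg.cho_solve(cf, X.T, check_finite=False)  # p x n
        h = w * np.einsum("ji,ji->i", X.T, V)
        score = X.T @ (y - mu + h * (0.5 - mu))
        i_free = info[np.ix_(free, free)]
        try:
            delta_free = np.linalg.solve(i_free, score[free])
        except np.linalg.LinAlgError:
            delta_free = np.linalg.lstsq(i_free, score[free], rcond=None)[0]
        delta = np.zeros(p)
        delta[free] = delta_free
        # step-halving keeps the penalized likelihood monotone
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            pll_new, mu_new, info_new = _pen_loglik(X, y, cand)
            if pll_new >= pll - 1e-12:
                break
            step *= 0.5
        else:
            converged = True
            break
        moved = step * np.max(np.abs(delta))
        improve = pll_new - pll
        beta, pll, mu, info = cand, pll_new, mu_new, info_new
        if moved < tol or (improve < 1e-10 and moved < 1e-6):
            converged = True
            break

    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    return FirthFit(beta=beta, se=se, pen_loglik=pll, converged=converged, n_iter=it)


def _design(burden: np.ndarray, covs: Optional[CovariateSet]) -> np.ndarray:
    """Intercept + standardized covariates + burden (last column).

    Covariates are centered and scaled internally, which leaves the burden
    coefficient untouched. Collinear covariate columns are dropped with a
    warning.
    """
    n = burden.shape[0]
    blocks = [np.ones((n, 1))]
    if covs is not None and covs.frame.shape[1]:
        C = covs.frame.to_numpy(dtype=float)
        sd = C.std(axis=0)
        mean = C.mean(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Cs = (C - mean) / sd_safe
        # rank-check via pivoted QR on [1 | covariates]
        q, r, piv = linalg.qr(
            np.hstack([np.ones((n, 1)), Cs]), mode="economic", pivoting=True
        )
        diag = np.abs(np.diag(r))
        good = diag > max(n, diag.size) * np.finfo(float).eps * diag.max()
        keep_cols = sorted(piv[good][piv[good] > 0] - 1)
        if len(keep_cols) < Cs.shape[1]:
            dropped = [covs.frame.columns[j] for j in range(Cs.shape[1]) if j not in keep_cols]
            warnings.warn(f"dropping collinear covariates: {dropped}", stacklevel=3)
        blocks.append(Cs[:, keep_cols])
    blocks.append(burden.reshape(-1, 1).astype(float))
    return np.hstack(blocks)


def fit_burden_test(
    burden_col: Sequence[int],
    pheno_col: Sequence[int],
    covs: Optional[CovariateSet] = None,
    t: Optional[ThresholdConfig] = None,
    start: Optional[np.ndarray] = None,
) -> tuple[float, float, float, float]:
    """Firth logistic test of phenotype on burden + covariates.

    Returns ``(beta, se, z, p)`` for the burden coefficient. ``z`` is signed
    (likelihood-ratio signed root by default); ``p`` is two-sided. Raises
    :class:`ConstantPhenotypeError` on a constant phenotype and ``ValueError``
    when there are no carriers.
    """
    t = t or ThresholdConfig()
    burden = np.asarray(burden_col, dtype=np.int8)
    y = np.asarray(pheno_col, dtype=float)
    if burden.sum() < 1:
        raise ValueError("no carriers: burden test undefined")
    if y.min() == y.max():
        raise ConstantPhenotypeError("phenotype is constant")

    X = _design(burden, covs)
    k = X.shape[1] - 1  # burden index

    null_start = None
    if start is not None:
        null_start = np.array(start, dtype=float)
    fit0 = firth_logistic(X, y, fixed_zero=[k], start=null_start)
    start1 = fit0.beta.copy()
    fit1 = firth_logistic(X, y, start=start1)

    beta = float(fit1.beta[k])
    se = float(fit1.se[k])
    if t.p_method == "wald":
        z = beta / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        stat = max(0.0, 2.0 * (fit1.pen_loglik - fit0.pen_loglik))
        z = float(np.sign(beta) * np.sqrt(stat)) if beta != 0 else 0.0
        p = float(stats.chi2.sf(stat, df=1))
    return beta, se, z, max(p, np.nextafter(0, 1))


def contingency_stats(
    burden_col: Sequence[int], pheno_col: Sequence[int]
) -> tuple[int, int, int, int, float]:
    """2x2 counts and odds ratio for one gene-phenotype pair.

    ``a`` carrier cases, ``b`` carrier controls, ``c`` non-carrier cases,
    ``d`` non-carrier controls. OR = (a*d)/(b*c); when any cell is zero the
    Haldane-Anscombe 0.5 correction is added to every cell, keeping the OR
    finite.
    """
    burden = np.asarray(burden_col, dtype=bool)
    y = np.asarray(pheno_col, dtype=bool)
    a = int(np.sum(burden & y))
    b = int(np.sum(burden & ~y))
    c = int(np.sum(~burden & y))
    d = int(np.sum(~burden & ~y))
    if min(a, b, c, d) == 0:
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsr = (a * d) / (b * c)
    return a, b, c, d, float(oddsr)


def compute_ppv(
    burden_col: Sequence[int],
    pheno_col: Sequence[int],
    ages: Sequence[float],
    stratum: str = "all",
    age_cut: float = 60.0,
) -> tuple[Optional[float], int]:
    """Positive predictive value: carrier cases / carriers within a stratum.

    ``stratum`` is ``"all"`` or ``"sixty_plus"`` (current age >= ``age_cut``).
    Returns ``(ppv, carrier_cases)``; ``ppv`` is ``None`` — a distinguished
    undefined value, not zero — when the stratum holds no carriers.
    """
    burden = np.asarray(burden_col, dtype=bool)
    y = np.asarray(pheno_col, dtype=bool)
    if stratum == "sixty_plus":
        mask = np.asarray(ages, dtype=float) >= age_cut
    elif stratum == "all":
        mask = np.ones_like(burden, dtype=bool)
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    carriers = burden & mask
    n_carriers = int(carriers.sum())
    carrier_cases = int(np.sum(carriers & y))
    if n_carriers == 0:
        return None, 0
    return carrier_cases / n_carriers, carrier_cases


@dataclass
class CohortAssocResult:
    """One cohort's full result for a (gene, phecode, model) triple."""

    gene_id: str
    phecode: str
    model: str
    n_samples: int
    a: int
    b: int
    c: int
    d: int
    beta: float
    se: float
    z: float
    p: float
    odds_ratio: float
    ppv_all_ages: Optional[float]
    ppv_60plus: Optional[float]
    carrier_cases_60plus: int

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_controls(self) -> int:
        return self.b + self.d

    @property
    def n_carriers(self) -> int:
        return self.a + self.b


def associate_pair(
    gene_id: str,
    phecode: str,
    model: str,
    burden_col: Sequence[int],
    pheno_col: Sequence[int],
    ages: Sequence[float],
    covs: Optional[CovariateSet],
    t: Optional[ThresholdConfig] = None,
    start: Optional[np.ndarray] = None,
) -> CohortAssocResult:
    """Run the burden test plus table statistics for one triple."""
    t = t or ThresholdConfig()
    beta, se, z, p = fit_burden_test(burden_col, pheno_col, covs, t, start=start)
    a, b, c, d, oddsr = contingency_stats(burden_col, pheno_col)
    ppv_all, _ = compute_ppv(burden_col, pheno_col, ages, "all", t.age_stratum_cut)
    ppv_60, cc60 = compute_ppv(
        burden_col, pheno_col, ages, "sixty_plus", t.age_stratum_cut
    )
    return CohortAssocResult(
        gene_id=gene_id,
        phecode=phecode,
        model=model,
        n_samples=len(burden_col),
        a=a,
        b=b,
        c=c,
        d=d,
        beta=beta,
        se=se,
        z=z,
        p=p,
        odds_ratio=oddsr,
        ppv_all_ages=ppv_all,
        ppv_60plus=ppv_60,
        carrier_cases_60plus=cc60,
    )
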