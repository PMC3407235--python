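"""Cohort-level statistics: phenotype classification, prevalence chi-square,
one-way ANOVA with Fisher's protected LSD, orthogonal polynomial photoperiod
contrasts, and simple/multiple least-squares regression.

Reproductive phenotype follows the study's rules: in photoperiods <= 12 L an
animal that keeps developed gonads (week-12 estimated testis volume >= 300)
AND summer pelage (fur score 1) is a short-day nonresponder (SD-NR), anyone
else a responder (SD-R); at 13 L and 14 L animals are labelled by the same
ETV cut (developed vs undeveloped) without the responder designation; 15 L
animals are long-day controls.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import SingularDesignError, ValidationError
from .schedule import AnimalMetadata

ETV_DEVELOPED = 300.0

#: standard 7-level orthogonal polynomial contrast codes, ordered 9 L .. 15 L
CONTRAST_CODES = {
    "linear": np.array([-3, -2, -1, 0, 1, 2, 3], dtype=float),
    "quadratic": np.array([5, 0, -3, -4, -3, 0, 5], dtype=float),
    "cubic": np.array([-1, 1, 1, 0, -1, -1, 1], dtype=float),
}
PHOTOPERIOD_ORDER = (9, 10, 11, 12, 13, 14, 15)


def classify_phenotype(meta: AnimalMetadata) -> str:
    """Reproductive phenotype label from photoperiod, testis volume and pelage."""
    L = meta.photoperiod_L
    developed = meta.etv_week12 >= ETV_DEVELOPED
    if L <= 12:
        return "SD-NR" if developed and meta.fur_score == 1 else "SD-R"
    if L == 13:
        return "13L+" if developed else "13L-"
    if L == 14:
        return "14L-developed" if developed else "14L-undeveloped"
    return "LD"


@dataclass
class ContingencyResult:
    table: np.ndarray  # 2x2 observed counts
    chi2: float
    df: int
    p: float


def prevalence_chi2(a_yes: int, a_no: int, b_yes: int, b_no: int) -> ContingencyResult:
    """Pearson chi-square on a 2x2 prevalence table, WITHOUT continuity correction.

    chi^2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with p from chi^2 on 1 df.
    """
    a, b, c, d = (int(x) for x in (a_yes, a_no, b_yes, b_no))
    if min(a, b, c, d) < 0:
        raise ValidationError("counts must be nonnegative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValidationError("chi-square undefined: a margin is zero")
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    return ContingencyResult(
        table=np.array([[a, b], [c, d]]),
        chi2=float(chi2),
        df=1,
        p=float(sps.chi2.sf(chi2, 1)),
    )


@dataclass
class ContrastResult:
    t_linear: float  # absolute t values
    t_quadratic: float
    t_cubic: float
    p_linear: float
    p_quadratic: float
    p_cubic: float
    codes: Dict[str, np.ndarray]


def polynomial_contrasts(
    values: Sequence[float],
    photoperiod_L: Sequence[float],
    per_animal: bool = True,
) -> ContrastResult:
    """Linear/quadratic/cubic photoperiod trend tests across the 7 groups.

    The three orthogonal polynomial codes are assigned to each animal by its
    photoperiod and entered jointly as regressors on the per-animal outcome
    (default); ``per_animal=False`` runs the same model on the 7 group means.
    Reports |t| and p per contrast.
    """
    y = np.asarray(values, float)
    L = np.asarray(photoperiod_L, float)
    if y.shape != L.shape:
        raise ValidationError("values and photoperiods differ in length")
    keep = ~np.isnan(y)
    y, L = y[keep], L[keep]
    present = set(np.unique(L).astype(int).tolist())
    if not set(PHOTOPERIOD_ORDER) <= present:
        missing = sorted(set(PHOTOPERIOD_ORDER) - present)
        raise ValidationError(f"missing photoperiod group(s): {missing}")

    if not per_animal:
        y = np.array([y[L == g].mean() for g in PHOTOPERIOD_ORDER])
        L = np.array(PHOTOPERIOD_ORDER, float)

    idx = np.searchsorted(np.array(PHOTOPERIOD_ORDER, float), L)
    X = np.column_stack(
        [np.ones_like(y)] + [CONTRAST_CODES[k][idx] for k in ("linear", "quadratic", "cubic")]
    )
    n, p = X.shape
    if n <= p:
        raise ValidationError("need more observations than contrast regressors")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise SingularDesignError("contrast design is rank deficient")
    resid = y - X @ beta
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if ssr <= 1e-12 * max(sst, 1e-300):
        # perfect fit up to float noise: a numerically-zero coefficient
        # carries t = 0, a real one t = inf
        scale = max(float(np.abs(beta).max()), 1.0)
        tvals = np.where(np.abs(beta) <= 1e-10 * scale, 0.0, np.inf)
    else:
        mse = ssr / (n - p)
        cov = mse * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), n - p)
    return ContrastResult(
        t_linear=float(abs(tvals[1])),
        t_quadratic=float(abs(tvals[2])),
        t_cubic=float(abs(tvals[3])),
        p_linear=float(pvals[1]),
        p_quadratic=float(pvals[2]),
        p_cubic=float(pvals[3]),
        codes={k: v.copy() for k, v in CONTRAST_CODES.items()},
    )


@dataclass
class RegressionResult:
    R: Optional[np.ndarray]  # Pearson correlation per predictor (simple sense)
    R2: float
    b: np.ndarray  # unstandardized coefficients (excluding intercept)
    SE: np.ndarray
    beta: np.ndarray  # standardized coefficients
    intercept: float
    see: float  # standard error of the estimate
    F: float
    df: Tuple[int, int]
    p: float
    p_coef: np.ndarray


def regress(y, predictors, names: Optional[List[str]] = None) -> RegressionResult:
    """Ordinary least-squares regression of ``y`` on one or more predictors.

    ``predictors`` is an (n, p) array or a sequence of columns. Reports the
    zero-order Pearson R per predictor, unstandardized b with SE, standardized
    beta (b * sd_x / sd_y), R^2, omnibus F and the standard error of the
    estimate sqrt(SSR / (n - p - 1)).
    """
    y = np.asarray(y, float)
    X = np.asarray(predictors, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n:
        raise ValidationError("y and predictors differ in length")
    if n <= p + 1:
        raise ValidationError("need n > p + 1 observations")
    Xd = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(Xd)
    if rank < p + 1:
        raise SingularDesignError("design matrix is rank deficient")
    beta_hat, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta_hat
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    dfe = n - p - 1
    mse = ssr / dfe
    cov = mse * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta_hat[1:] / se, np.inf * np.sign(beta_hat[1:]))
        pvals = 2.0 * sps.t.sf(np.abs(tvals), dfe)
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    std_beta = beta_hat[1:] * sx / sy if sy > 0 else np.full(p, np.nan)
    if ssr <= 1e-12 * max(sst, 1e-300):
        F, p_omni = float("inf"), 0.0
    else:
        F = ((sst - ssr) / p) / (ssr / dfe)
        p_omni = float(sps.f.sf(F, p, dfe))
    R = np.array([sps.pearsonr(X[:, j], y)[0] for j in range(p)]) if sy > 0 else None
    return RegressionResult(
        R=R,
        R2=float(r2),
        b=beta_hat[1:],
        SE=se,
        beta=std_beta,
        intercept=float(beta_hat[0]),
        see=float(np.sqrt(mse)),
        F=float(F),
        df=(p, dfe),
        p=p_omni,
        p_coef=pvals,
    )


@dataclass
class AnovaResult:
    F: float
    df: Tuple[int, int]
    p: float
    mse: float
    group_means: Dict[str, float]
    pairwise_p: Dict[Tuple[str, str], float]  # Fisher's LSD vs the reference group


def anova_plsd(
    groups: Mapping[str, Sequence[float]], reference: Optional[str] = None
) -> AnovaResult:
    """One-way ANOVA plus Fisher's (protected) LSD pairwise tests.

    Pairwise comparisons use the pooled MSE t statistic against ``reference``
    (default: the first group); with exactly two groups this reduces to the
    unpaired two-tailed t test.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need at least 2 groups")
    data = {k: np.asarray(v, float)[~np.isnan(np.asarray(v, float))] for k, v in groups.items()}
    if any(v.size < 2 for v in data.values()):
        raise ValidationError("every group needs n >= 2")
    all_y = np.concatenate(list(data.values()))
    if np.allclose(all_y, all_y[0]):
        raise ValidationError("degenerate: all observations identical")
    k = len(names)
    N = all_y.size
    grand = all_y.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_w = k - 1, N - k
    mse = ss_within / df_w
    F = (ss_between / df_b) / mse if mse > 0 else float("inf")
    p = float(sps.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0

    ref = names[0] if reference is None else reference
    pairwise: Dict[Tuple[str, str], float] = {}
    for name in names:
        if name == ref:
            continue
        a, b = data[ref], data[name]
        if mse > 0:
            tstat = (a.mean() - b.mean()) / np.sqrt(mse * (1 / a.size + 1 / b.size))
            pairwise[(ref, name)] = float(2.0 * sps.t.sf(abs(tstat), df_w))
        else:
            pairwise[(ref, name)] = 0.0 if a.mean() != b.mean() else 1.0
    return AnovaResult(
        F=float(F),
        df=(df_b, df_w),
        p=p,
        mse=float(mse),
        group_means={kk: float(v.mean()) for kk, v in data.items()},
        pairwise_p=pairwise,
    )
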