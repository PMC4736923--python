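"""Genetic association layer.

Hardy-Weinberg testing, genotype dummy coding, and maximum-likelihood
proportional-odds (cumulative-logit) ordinal regression with Nagelkerke
R-squared and a likelihood-ratio parallel-lines check.

Sign convention
---------------
The model is ``P(Y <= j | x) = sigmoid(theta_j - x @ beta)``, so a positive
coefficient — and an odds ratio above 1 — means the covariate INCREASES the
odds of a higher grade. This is the convention in which the reported odds
ratios read "having the genotype increased the odds of a higher grade";
note that some software reports the opposite sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize as spoptimize
from scipy import stats as spstats

from .errors import ConvergenceError, ValidationError
from .stats import TestResult

__all__ = [
    "HWEResult",
    "OrdinalFitResult",
    "GenotypeCoding",
    "allele_frequency",
    "hwe_chi2",
    "code_genotype_dummies",
    "fit_proportional_odds",
    "nagelkerke_r2",
    "parallel_lines_test",
]


def _clean_genotypes(genotypes: Sequence) -> np.ndarray:
    vals = []
    for g in genotypes:
        if g is None:
            continue
        g = float(g)
        if math.isnan(g):
            continue
        if g not in (0.0, 1.0, 2.0):
            raise ValidationError(f"genotype must be 0/1/2 or missing, got {g!r}")
        vals.append(int(g))
    return np.asarray(vals, dtype=np.int64)


def allele_frequency(genotypes: Sequence) -> float:
    """Derived-allele frequency (2*hom + het) / (2n), missing dropped."""
    g = _clean_genotypes(genotypes)
    if len(g) == 0:
        raise ValidationError("no genotypes left after dropping missing values")
    return float((2 * np.sum(g == 2) + np.sum(g == 1)) / (2 * len(g)))


@dataclass(frozen=True)
class HWEResult:
    """Hardy-Weinberg chi-square (1 df, no continuity correction)."""

    observed: tuple[int, int, int]  # (ancestral hom, het, derived hom)
    frequency: float  # derived-allele frequency
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p: float
    degenerate: bool


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> HWEResult:
    """Test genotype counts (AA ancestral hom, Aa het, aa derived hom)
    against Hardy-Weinberg proportions p^2 / 2pq / q^2."""
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValidationError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValidationError("no individuals")
    p_hat = (2 * counts[2] + counts[1]) / (2 * n)
    q_hat = 1.0 - p_hat
    expected = (n * q_hat**2, n * 2 * p_hat * q_hat, n * p_hat**2)
    degenerate = p_hat in (0.0, 1.0)
    if degenerate:
        chi2 = 0.0
    else:
        chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    p = float(spstats.chi2.sf(chi2, 1))
    return HWEResult(
        observed=counts,
        frequency=p_hat,
        expected=expected,
        chi2=float(chi2),
        df=1,
        p=p,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class GenotypeCoding:
    """Dummy-coded genotype design (reference = ancestral homozygote)."""

    X: np.ndarray  # (n_kept, n_columns) indicator matrix
    columns: tuple[str, ...]
    kept_index: np.ndarray  # positions in the input that survive
    class_counts: dict[int, int]  # counts among non-missing input
    dropped_classes: dict[int, int]  # class -> excluded individual count
    n_missing: int


_CLASS_COLUMN = {1: "het", 2: "hom_derived"}


def code_genotype_dummies(
    genotypes: Sequence, min_class_count: int = 5
) -> GenotypeCoding:
    """Indicator columns for het and derived-homozygote genotypes.

    Genotype classes observed in fewer than `min_class_count` individuals
    are dropped and those individuals excluded from the design (mirroring
    the analysis rule used when a derived-homozygote class is nearly empty).
    The ancestral-homozygote reference class cannot be dropped.
    """
    raw = []
    for g in genotypes:
        if g is None or (isinstance(g, float) and math.isnan(g)):
            raw.append(None)
        else:
            gi = int(g)
            if gi not in (0, 1, 2):
                raise ValidationError(f"genotype must be 0/1/2 or missing, got {g!r}")
            raw.append(gi)
    counts = {c: sum(1 for g in raw if g == c) for c in (0, 1, 2)}
    if counts[0] < min_class_count:
        raise ValidationError(
            f"ancestral-homozygote reference class has {counts[0]} individuals "
            f"(< {min_class_count}); cannot form a reference"
        )
    dropped = {
        c: counts[c] for c in (1, 2) if 0 < counts[c] < min_class_count
    }
    keep_classes = [c for c in (1, 2) if counts[c] >= min_class_count]
    kept_index = np.array(
        [i for i, g in enumerate(raw) if g is not None and g not in dropped],
        dtype=np.int64,
    )
    kept = [raw[i] for i in kept_index]
    X = np.column_stack(
        [np.asarray([g == c for g in kept], dtype=float) for c in keep_classes]
    ) if keep_classes else np.empty((len(kept), 0))
    return GenotypeCoding(
        X=X,
        columns=tuple(_CLASS_COLUMN[c] for c in keep_classes),
        kept_index=kept_index,
        class_counts=counts,
        dropped_classes=dropped,
        n_missing=sum(1 for g in raw if g is None),
    )


# ---------------------------------------------------------------------------
# Proportional-odds regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinalFitResult:
    """Maximum-likelihood cumulative-logit fit with parallel slopes."""

    thresholds: np.ndarray  # strictly increasing, length J-1
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    odds_ratios: np.ndarray
    loglik: float
    null_loglik: float
    nagelkerke_r2: float
    n: int
    n_categories: int
    converged: bool
    separation_flag: bool
    covariate_names: tuple[str, ...]
    deviance: float
    pearson_chi2: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _prepare_outcome(y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    levels, yi = np.unique(y, return_inverse=True)
    if len(levels) < 2:
        raise ValidationError("outcome must have at least 2 observed levels")
    return yi, levels


class _POModel:
    """Negative log-likelihood machinery in raw (theta, beta) coordinates."""

    def __init__(self, yi: np.ndarray, X: np.ndarray, J: int):
        self.yi = yi
        self.X = X
        self.J = J
        self.n, self.p = X.shape

    def raw_nll_grad(self, theta: np.ndarray, beta: np.ndarray):
        J, yi, X = self.J, self.yi, self.X
        eta = X @ beta if self.p else np.zeros(self.n)
        theta_ext = np.concatenate(([-np.inf], theta, [np.inf]))
        za = theta_ext[yi + 1] - eta
        zb = theta_ext[yi] - eta
        Fa = np.where(np.isinf(za), 1.0, _sigmoid(np.where(np.isinf(za), 0.0, za)))
        Fb = np.where(np.isinf(zb), 0.0, _sigmoid(np.where(np.isinf(zb), 0.0, zb)))
        pi = np.clip(Fa - Fb, 1e-300, None)
        nll = -float(np.log(pi).sum())
        fa = np.where(np.isinf(za), 0.0, Fa * (1.0 - Fa))
        fb = np.where(np.isinf(zb), 0.0, Fb * (1.0 - Fb))
        wa = fa / pi
        wb = fb / pi
        g_theta = np.zeros(J - 1)
        np.add.at(g_theta, np.clip(yi, 0, J - 2), np.where(yi <= J - 2, wa, 0.0))
        np.add.at(g_theta, np.clip(yi - 1, 0, J - 2), np.where(yi >= 1, -wb, 0.0))
        g_beta = X.T @ (wb - wa) if self.p else np.zeros(0)
        return nll, -g_theta, -g_beta

    # reparameterization guaranteeing ordered thresholds:
    # theta_1 = t0; theta_j = t0 + sum_{k<=j} exp(d_k)
    def unpack(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        J = self.J
        t0 = params[0]
        deltas = params[1 : J - 1]
        theta = t0 + np.concatenate(([0.0], np.cumsum(np.exp(deltas))))
        beta = params[J - 1 :]
        return theta, beta

    def nll_grad(self, params: np.ndarray):
        theta, beta = self.unpack(params)
        nll, g_theta, g_beta = self.raw_nll_grad(theta, beta)
        J = self.J
        g = np.empty_like(params)
        g[0] = g_theta.sum()
        deltas = params[1 : J - 1]
        # d theta_j / d delta_k = exp(delta_k) for j > k-th position
        suffix = np.cumsum(g_theta[::-1])[::-1]
        g[1 : J - 1] = np.exp(deltas) * suffix[1:]
        g[J - 1 :] = g_beta
        return nll, g


def _null_loglik(yi: np.ndarray, J: int) -> tuple[float, np.ndarray]:
    n = len(yi)
    counts = np.bincount(yi, minlength=J).astype(float)
    if np.any(counts == 0):
        raise ValidationError("every outcome level must be observed at least once")
    ll0 = float((counts * np.log(counts / n)).sum())
    cum = np.cumsum(counts)[:-1] / n
    thresholds = np.log(cum / (1.0 - cum))
    return ll0, thresholds


def nagelkerke_r2(ll0: float, ll1: float, n: int) -> float:
    """Nagelkerke pseudo-R2 from null and fitted log-likelihoods."""
    if n <= 0:
        raise ValidationError("n must be positive")
    if ll1 < ll0 - 1e-8:
        raise ValidationError("fitted log-likelihood below null log-likelihood")
    r2_cs = 1.0 - math.exp(2.0 * (ll0 - ll1) / n)
    denom = 1.0 - math.exp(2.0 * ll0 / n)
    if denom <= 0.0:
        raise ValidationError("null model has likelihood 1; R2 undefined")
    return min(1.0, max(0.0, r2_cs / denom))


def _numerical_hessian(model: _POModel, theta: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of the NLL in raw (theta, beta) space."""
    x0 = np.concatenate([theta, beta])
    k = len(x0)

    def grad(x):
        t, b = x[: model.J - 1], x[model.J - 1 :]
        _, gt, gb = model.raw_nll_grad(t, b)
        return np.concatenate([gt, gb])

    H = np.zeros((k, k))
    for i in range(k):
        h = 1e-5 * max(1.0, abs(x0[i]))
        xp = x0.copy()
        xm = x0.copy()
        xp[i] += h
        xm[i] -= h
        H[:, i] = (grad(xp) - grad(xm)) / (2 * h)
    return 0.5 * (H + H.T)


def fit_proportional_odds(
    y: Sequence,
    X: np.ndarray | Sequence[Sequence[float]] | None = None,
    covariate_names: Sequence[str] | None = None,
    gtol: float = 1e-8,
    max_iter: int = 200,
) -> OrdinalFitResult:
    """Fit ``P(Y <= j | x) = sigmoid(theta_j - x beta)`` by maximum likelihood.

    Odds ratios ``exp(beta)`` read as the multiplicative change in the odds
    of a HIGHER grade per unit covariate. Thresholds are kept strictly
    increasing via the reparameterization theta_j = theta_1 + cumsum(exp(d)).
    """
    yi, levels = _prepare_outcome(y)
    J = len(levels)
    if X is None:
        X = np.empty((len(yi), 0))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(yi):
        X = X.T
    if X.shape[0] != len(yi):
        raise ValidationError("X row count must match the outcome length")
    n, p = X.shape
    if p:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
        if rank < p + 1:
            raise ValidationError("collinear covariate columns (or a constant column)")
    names = tuple(covariate_names) if covariate_names else tuple(
        f"x{i + 1}" for i in range(p)
    )
    if len(names) != p:
        raise ValidationError("covariate_names length must match X columns")

    ll0, theta0 = _null_loglik(yi, J)
    model = _POModel(yi, X, J)
    d0 = np.log(np.maximum(np.diff(theta0), 1e-3))
    start = np.concatenate([[theta0[0]], d0, np.zeros(p)])

    trace: list[float] = []

    def fun(params):
        nll, g = model.nll_grad(params)
        trace.append(nll)
        return nll, g

    res = spoptimize.minimize(
        fun,
        start,
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    theta, beta = model.unpack(res.x)
    _, g_theta, g_beta = model.raw_nll_grad(theta, beta)
    grad_norm = float(np.linalg.norm(np.concatenate([g_theta, g_beta])))
    converged = bool(res.success) or grad_norm < 1e-5
    if not converged:
        raise ConvergenceError(
            f"proportional-odds fit did not converge (|grad| = {grad_norm:.3g})",
            trace=trace[-20:],
        )
    ll1 = -float(res.fun)

    H = _numerical_hessian(model, theta, beta)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(J - 1 + p, np.nan)
    se_beta = se_all[J - 1 :]
    separation = bool(np.any(np.abs(beta) > 15.0) or np.any(se_beta > 100.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta / se_beta
    pvals = 2.0 * spstats.norm.sf(np.abs(zvals))

    # goodness-of-fit residual statistics (per-observation cells)
    eta = X @ beta if p else np.zeros(n)
    cumF = np.concatenate(
        [
            np.zeros((n, 1)),
            _sigmoid(theta[None, :] - eta[:, None]),
            np.ones((n, 1)),
        ],
        axis=1,
    )
    probs = np.diff(cumF, axis=1)
    obs = np.zeros((n, J))
    obs[np.arange(n), yi] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = -2.0 * float(np.sum(obs * np.log(np.clip(probs, 1e-300, None))))
        pearson = float(np.sum((obs - probs) ** 2 / np.clip(probs, 1e-300, None)))

    return OrdinalFitResult(
        thresholds=theta,
        beta=beta,
        se=se_beta,
        z=zvals,
        p=pvals,
        odds_ratios=np.exp(beta),
        loglik=ll1,
        null_loglik=ll0,
        nagelkerke_r2=nagelkerke_r2(ll0, ll1, n) if p else 0.0,
        n=n,
        n_categories=J,
        converged=converged,
        separation_flag=separation,
        covariate_names=names,
        deviance=dev,
        pearson_chi2=pearson,
    )


def _unconstrained_nll_grad(params: np.ndarray, yi: np.ndarray, X: np.ndarray, J: int):
    """Cumulative model with a separate slope vector per threshold."""
    n, p = X.shape
    theta = params[: J - 1]
    B = params[J - 1 :].reshape(J - 1, p)
    eta = X @ B.T  # (n, J-1): eta_{ij} for threshold j
    Z = theta[None, :] - eta
    F = _sigmoid(Z)
    # pick F at threshold y (upper) and y-1 (lower)
    upper = np.where(yi <= J - 2, F[np.arange(n), np.clip(yi, 0, J - 2)], 1.0)
    lower = np.where(yi >= 1, F[np.arange(n), np.clip(yi - 1, 0, J - 2)], 0.0)
    pi = np.clip(upper - lower, 1e-12, None)
    nll = -float(np.log(pi).sum())
    g = np.zeros_like(params)
    fu = np.where(yi <= J - 2, upper * (1.0 - upper), 0.0) / pi
    fl = np.where(yi >= 1, lower * (1.0 - lower), 0.0) / pi
    for j in range(J - 1):
        sel_u = yi == j
        sel_l = yi == j + 1
        g[j] = -(fu[sel_u].sum() - fl[sel_l].sum())
        gb = X[sel_u].T @ fu[sel_u] - X[sel_l].T @ fl[sel_l]
        g[J - 1 + j * p : J - 1 + (j + 1) * p] = gb
    return nll, g


def parallel_lines_test(
    y: Sequence, X: np.ndarray | Sequence[Sequence[float]]
) -> TestResult:
    """Likelihood-ratio test of parallel slopes.

    Compares the proportional-odds fit against the cumulative-logit model
    with a separate slope vector at every threshold;
    df = (J - 2) * n_covariates. With J = 2 the two models coincide and the
    test is not applicable (p is None).
    """
    yi, levels = _prepare_outcome(y)
    J = len(levels)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(yi):
        X = X.T
    n, p = X.shape
    if p == 0:
        raise ValidationError("parallel-lines test needs at least one covariate")
    if J == 2:
        return TestResult(
            statistic=0.0, df=0, p=None, method="parallel-lines LR (not applicable, J=2)"
        )
    po = fit_proportional_odds(y, X)
    start = np.concatenate([po.thresholds, np.tile(po.beta, J - 1)])
    res = spoptimize.minimize(
        _unconstrained_nll_grad,
        start,
        args=(yi, X, J),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-7, "maxiter": 500},
    )
    ll_full = -float(res.fun)
    lr = max(0.0, 2.0 * (ll_full - po.loglik))
    df = (J - 2) * p
    pval = float(spstats.chi2.sf(lr, df))
    return TestResult(statistic=lr, df=df, p=pval, method="parallel-lines LR")
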