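"""Dirichlet-multinomial (DM) distribution: log-pmf, sampling, and ML fitting.

The DM distribution models multicategory read counts with extra-multinomial
(between-sample) variation.  A sample's taxon proportions are drawn from a
Dirichlet distribution and reads are then drawn multinomially, giving the
compound pmf

    P(s | alpha) = N! / prod_t s_t!
                   * Gamma(A) / Gamma(A + N)
                   * prod_t Gamma(alpha_t + s_t) / Gamma(alpha_t),

with concentrations ``alpha_t > 0``, ``A = sum_t alpha_t``, ``N = sum_t s_t``.
We use the (pi, theta) parameterization common in microbiome work:
``pi_t = alpha_t / A`` is the expected proportion of taxon ``t`` and
``theta = 1 / (1 + A)`` the overdispersion; ``theta -> 0`` recovers the
plain multinomial and ``theta -> 1`` maximal overdispersion.

All likelihood arithmetic is done in log space with log-gamma functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, polygamma, psi

__all__ = ["DMParams", "FitResult", "dm_log_pmf", "dm_log_pmf_rows", "dm_sample", "fit_dm", "mom_params"]

logger = logging.getLogger(__name__)

#: hard bounds keeping every log-gamma argument finite and positive
THETA_MIN = 1e-10
THETA_MAX = 1.0 - 1e-10

#: a fit ending below this overdispersion is reported as a boundary solution
#: (the data are multinomial-compatible and the theta MLE sits at 0)
THETA_BOUNDARY = 1e-7

#: fitting tolerances
LOGLIK_TOL = 1e-8
MAX_ITER = 500


@dataclass(frozen=True)
class DMParams:
    """One class's fitted DM distribution.

    Parameters
    ----------
    pi : ndarray
        Expected taxon proportions, strictly positive, summing to 1.
    theta : float
        Overdispersion in (0, 1).
    """

    pi: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.ndim != 1 or pi.size < 2:
            raise ValueError("pi must be a 1-d vector with at least 2 taxa")
        if np.any(pi <= 0):
            raise ValueError("every pi_t must be strictly positive")
        if abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError(f"pi must sum to 1 (got {pi.sum()!r})")
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta must lie strictly in (0, 1), got {self.theta!r}")

    @property
    def alpha(self) -> np.ndarray:
        """Concentration vector ``alpha_t = pi_t (1 - theta) / theta``."""
        return self.pi * (1.0 - self.theta) / self.theta

    @property
    def n_taxa(self) -> int:
        return self.pi.size

    @classmethod
    def from_alpha(cls, alpha: np.ndarray) -> "DMParams":
        alpha = np.asarray(alpha, dtype=float)
        total = alpha.sum()
        theta = float(np.clip(1.0 / (1.0 + total), THETA_MIN, THETA_MAX))
        pi = alpha / total
        return cls(pi=pi / pi.sum(), theta=theta)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood DM fit."""

    params: DMParams
    loglik: float
    n_iter: int
    converged: bool
    init_loglik: float = field(default=float("nan"), repr=False)


def _validate_counts(s: np.ndarray, n_taxa: int | None = None) -> np.ndarray:
    s = np.asarray(s)
    if np.any(s < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(s.dtype, np.integer):
        rounded = np.rint(s)
        if not np.allclose(s, rounded):
            raise ValueError("counts must be integers")
        s = rounded.astype(np.int64)
    if n_taxa is not None and s.shape[-1] != n_taxa:
        raise ValueError(
            f"dimension mismatch: count vector has {s.shape[-1]} taxa, parameters have {n_taxa}"
        )
    return s.astype(np.int64)


def dm_log_pmf(s: np.ndarray, params: DMParams) -> float:
    """Log-probability of one count vector under a DM distribution.

    Parameters
    ----------
    s : array of non-negative integers, length matching ``params.pi``.
    params : DMParams

    Returns
    -------
    float
        ``log P(s)``, always finite and <= 0.
    """
    s = _validate_counts(s, params.n_taxa)
    if s.ndim != 1:
        raise ValueError("dm_log_pmf expects a single count vector; use dm_log_pmf_rows for matrices")
    if s.sum() < 1:
        raise ValueError("total read count N must be >= 1")
    return float(dm_log_pmf_rows(s[None, :], params)[0])


def dm_log_pmf_rows(counts: np.ndarray, params: DMParams) -> np.ndarray:
    """Vectorized :func:`dm_log_pmf` over the rows of a count matrix."""
    counts = _validate_counts(counts, params.n_taxa)
    alpha = params.alpha
    a_sum = alpha.sum()
    n = counts.sum(axis=1)
    coeff = gammaln(n + 1.0) - gammaln(counts + 1.0).sum(axis=1)
    return (
        coeff
        + gammaln(a_sum)
        - gammaln(a_sum + n)
        + (gammaln(counts + alpha) - gammaln(alpha)).sum(axis=1)
    )


def dm_sample(
    params: DMParams,
    n: int,
    depth: int | np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` count vectors: Dirichlet proportions, then multinomial reads.

    ``depth`` may be a single total-read count shared by all samples or a
    length-``n`` vector of per-sample totals.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depths = np.broadcast_to(np.asarray(depth, dtype=np.int64), (n,))
    if np.any(depths < 1):
        raise ValueError("every sampling depth must be >= 1")
    props = rng.dirichlet(params.alpha, size=n)
    out = np.empty((n, params.n_taxa), dtype=np.int64)
    for i in range(n):
        out[i] = rng.multinomial(depths[i], props[i])
    return out


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _loglik(counts: np.ndarray, row_totals: np.ndarray, const: float, alpha: np.ndarray) -> float:
    a_sum = alpha.sum()
    return float(
        const
        + counts.shape[0] * gammaln(a_sum)
        - gammaln(a_sum + row_totals).sum()
        + (gammaln(counts + alpha) - gammaln(alpha)).sum()
    )


def _gradient(counts: np.ndarray, row_totals: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    n_rows = counts.shape[0]
    a_sum = alpha.sum()
    return (
        psi(counts + alpha).sum(axis=0)
        - n_rows * psi(alpha)
        + n_rows * psi(a_sum)
        - psi(a_sum + row_totals).sum()
    )


def mom_params(counts: np.ndarray) -> DMParams:
    """Method-of-moments (pi, theta) estimate.

    pi is the pooled proportion vector; theta comes from the classical
    ANOVA-style moment estimator that contrasts between-sample and
    within-sample mean squares of the per-sample proportions.
    """
    counts = _validate_counts(counts)
    row_totals = counts.sum(axis=1).astype(float)
    n_rows = counts.shape[0]
    total = row_totals.sum()
    pi = counts.sum(axis=0) / total
    pi = np.clip(pi, 1e-12, None)
    pi = pi / pi.sum()
    props = counts / row_totals[:, None]
    if n_rows < 2:
        return DMParams(pi=pi, theta=0.01)
    msp = (row_totals[:, None] * (props - pi) ** 2).sum(axis=0) / (n_rows - 1)
    msg = (row_totals[:, None] * props * (1.0 - props)).sum(axis=0) / max(total - n_rows, 1.0)
    n_c = (total - (row_totals**2).sum() / total) / (n_rows - 1)
    denom = (msp + (n_c - 1.0) * msg).sum()
    theta = (msp - msg).sum() / denom if denom > 0 else 0.01
    if not np.isfinite(theta):
        theta = 0.01
    theta = float(np.clip(theta, 1e-6, 1.0 - 1e-6))
    return DMParams(pi=pi, theta=theta)


def fit_dm(
    counts: np.ndarray,
    alpha0: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = LOGLIK_TOL,
) -> FitResult:
    """Maximum-likelihood DM fit for the count rows of one class.

    Newton-Raphson on the concentration vector (the Hessian is diagonal plus
    rank one, so the Newton step is closed-form via Sherman-Morrison), falling
    back to the monotone fixed-point update whenever a Newton step would leave
    the feasible region or lower the likelihood.  Initialized at the
    method-of-moments estimate unless ``alpha0`` warm-starts it.

    Taxa with zero total count in ``counts`` get their concentration floored
    at ``0.5 / total_reads`` so held-out samples containing them never receive
    a -inf log-likelihood.
    """
    counts = _validate_counts(counts)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("fit_dm needs a 2-d count matrix with at least 2 rows")
    if counts.shape[1] < 2:
        raise ValueError("fit_dm needs at least 2 taxa")
    row_totals = counts.sum(axis=1)
    if np.any(row_totals < 1):
        raise ValueError("every row must contain at least one read")
    row_totals_f = row_totals.astype(float)
    const = float((gammaln(row_totals_f + 1.0) - gammaln(counts + 1.0).sum(axis=1)).sum())

    init = mom_params(counts)
    init_alpha = init.alpha if alpha0 is None else np.clip(np.asarray(alpha0, float), 1e-12, None)
    init_loglik = _loglik(counts, row_totals_f, const, init.alpha)

    alpha = init_alpha.copy()
    ll = _loglik(counts, row_totals_f, const, alpha)
    n_rows = counts.shape[0]
    a_max = (1.0 - THETA_MIN) / THETA_MIN  # theta clamp expressed on sum(alpha)
    converged = False
    hit_boundary = False
    it = 0
    for it in range(1, max_iter + 1):
        g = _gradient(counts, row_totals_f, alpha)
        a_sum = alpha.sum()
        # Hessian = diag(q) + c * ones ones^T
        q = polygamma(1, counts + alpha).sum(axis=0) - n_rows * polygamma(1, alpha)
        c = n_rows * polygamma(1, a_sum) - polygamma(1, a_sum + row_totals_f).sum()
        new_alpha = None
        with np.errstate(divide="ignore", invalid="ignore"):
            if np.all(q < 0):
                g_over_q = g / q
                b = c * g_over_q.sum() / (1.0 + c * (1.0 / q).sum())
                step = -(g_over_q - b / q)
                cand = alpha + step
                if np.all(np.isfinite(cand)) and np.all(cand > 0):
                    cand_ll = _loglik(counts, row_totals_f, const, cand)
                    if cand_ll >= ll:
                        new_alpha, new_ll = cand, cand_ll
        if new_alpha is None:
            # monotone fixed-point update on the concentrations
            num = psi(counts + alpha).sum(axis=0) - n_rows * psi(alpha)
            den = psi(alpha.sum() + row_totals_f).sum() - n_rows * psi(alpha.sum())
            cand = alpha * num / den
            cand = np.clip(cand, 1e-12, None)
            new_alpha = cand
            new_ll = _loglik(counts, row_totals_f, const, new_alpha)
        if not np.isfinite(new_ll):
            break
        delta = new_ll - ll
        alpha, ll = new_alpha, new_ll
        if alpha.sum() > a_max:
            hit_boundary = True
            break
        if abs(delta) < tol:
            converged = True
            break

    if alpha.sum() > a_max:
        alpha = alpha * (a_max / alpha.sum())
        hit_boundary = True
        ll = _loglik(counts, row_totals_f, const, alpha)

    # floor for taxa unseen in this class's training rows
    zero_cols = counts.sum(axis=0) == 0
    if np.any(zero_cols):
        eps = 0.5 / row_totals.sum()
        alpha = np.where(zero_cols, np.maximum(alpha, eps), alpha)
        ll = _loglik(counts, row_totals_f, const, alpha)

    params = DMParams.from_alpha(alpha)
    if hit_boundary or params.theta < THETA_BOUNDARY:
        converged = False
        logger.warning("DM fit ended at the overdispersion boundary (theta=%g)", params.theta)
    return FitResult(params=params, loglik=ll, n_iter=max(it, 1), converged=converged, init_loglik=init_loglik)
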