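"""Socioeconomic inequality measures for binary health outcomes.

The concentration index C of a health variable h with respect to a wealth
ranking is twice the weighted covariance between h and the fractional wealth
rank, divided by the mean of h:

    C = (2 / mu) * cov_w(h, r)

Negative values indicate concentration of h among the poor, positive among
the rich. For a binary h, C is bounded by [mu - 1, 1 - mu], which makes raw
values incomparable across populations with different means; two standard
bounds corrections are provided:

* Wagstaff:  W = C / (1 - mu)
* Erreygers: E = 4 * mu * C

which satisfy the identity E = 4 * mu * (1 - mu) * W for binary outcomes.

Standard errors come from the "convenient regression" formulation: weighted
least squares of a rescaled outcome on the fractional rank has the index as
its slope, so any robust covariance estimator for the slope yields an SE for
the index. The default is a cluster-robust (CR1, Stata-style small-sample
factor) sandwich clustered on the primary sampling unit.

The module also provides the Theil-T index (generalized entropy, alpha = 1)
with its exact additive decomposition into within- and between-group
components, used here to summarize dispersion of subnational coverage
estimates within and between countries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateOutcomeError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConcentrationResult",
    "TheilDecomposition",
    "weighted_fractional_rank",
    "concentration_index",
    "wagstaff_index",
    "erreygers_index",
    "index_inference",
    "theil_decompose",
]


@dataclass(frozen=True)
class ConcentrationResult:
    """Point estimates and 95% confidence bounds for the corrected indices.

    Attributes
    ----------
    mu : weighted mean of the binary outcome.
    ci_raw : uncorrected concentration index C.
    wagstaff, erreygers : bounds-corrected indices W and E.
    se_w, se_e : standard errors of W and E.
    lower_w, upper_w, lower_e, upper_e : 95% normal confidence bounds.
    n : number of observations used.
    n_clusters : number of PSU clusters (1 if the plain-SE fallback ran).
    """

    mu: float
    ci_raw: float
    wagstaff: float
    erreygers: float
    se_w: float
    se_e: float
    lower_w: float
    upper_w: float
    lower_e: float
    upper_e: float
    n: int
    n_clusters: int


@dataclass(frozen=True)
class TheilDecomposition:
    total: float
    within: float
    between: float


def _as_weights(weights, n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValidationError(f"weights have shape {w.shape}, expected ({n},)")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValidationError("weights must be finite and strictly positive")
    return w / w.sum()


def weighted_fractional_rank(wealth_scores, weights) -> np.ndarray:
    """Weighted fractional ranks in (0, 1) by ascending wealth.

    Each observation receives the cumulative normalized weight of all
    strictly poorer observations plus half its own normalized weight
    (the midpoint rule). Observations tied on wealth all receive the
    midpoint rank of their tied block, which makes the result invariant
    to the input ordering.
    """
    x = np.asarray(wealth_scores, dtype=float)
    if x.ndim != 1:
        raise ValidationError("wealth_scores must be one-dimensional")
    w = _as_weights(weights, x.size)
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws)
    # midpoint rank of each tied block: (cum before block) + (block weight)/2
    block_start = np.r_[True, xs[1:] != xs[:-1]]
    block_id = np.cumsum(block_start) - 1
    n_blocks = block_id[-1] + 1 if x.size else 0
    block_w = np.bincount(block_id, weights=ws, minlength=n_blocks)
    block_end = np.cumsum(block_w)
    block_rank = block_end - block_w / 2.0
    ranks_sorted = block_rank[block_id]
    ranks = np.empty_like(ranks_sorted)
    ranks[order] = ranks_sorted
    return ranks


def _weighted_cov(a: np.ndarray, b: np.ndarray, w_norm: np.ndarray) -> float:
    am = float(w_norm @ a)
    bm = float(w_norm @ b)
    return float(w_norm @ ((a - am) * (b - bm)))


def _check_binary(h) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if h.ndim != 1:
        raise ValidationError("outcome must be one-dimensional")
    if not np.isin(h, (0.0, 1.0)).all():
        raise ValidationError("outcome must be binary (0/1)")
    return h


def concentration_index(h, ranks, weights) -> float:
    """Raw concentration index C = (2/mu) * cov_w(h, r).

    Equals twice the signed area between the 45-degree line and the
    concentration curve when ``ranks`` are midpoint fractional ranks.
    """
    h = _check_binary(h)
    r = np.asarray(ranks, dtype=float)
    w = _as_weights(weights, h.size)
    mu = float(w @ h)
    if mu <= 0.0 or mu >= 1.0:
        raise DegenerateOutcomeError(
            f"concentration index undefined for degenerate outcome (mu={mu:g})"
        )
    return 2.0 / mu * _weighted_cov(h, r, w)


def wagstaff_index(c: float, mu: float) -> float:
    """Wagstaff bounds correction for a binary outcome: W = C / (1 - mu)."""
    if not 0.0 < mu < 1.0:
        raise DegenerateOutcomeError(f"Wagstaff index requires 0 < mu < 1 (mu={mu:g})")
    return c / (1.0 - mu)


def erreygers_index(c: float, mu: float) -> float:
    """Erreygers bounds correction for a binary outcome: E = 4 * mu * C."""
    if not 0.0 < mu < 1.0:
        raise DegenerateOutcomeError(f"Erreygers index requires 0 < mu < 1 (mu={mu:g})")
    return 4.0 * mu * c


def _wls_slope_sandwich(y, r, w_norm, cluster_ids, cluster: bool):
    """Slope and robust SE of weighted regression of y on [1, r].

    Cluster-robust (CR1 with Stata small-sample factor G/(G-1)*(N-1)/(N-k))
    when ``cluster``; HC1 otherwise.
    """
    n = y.size
    X = np.column_stack([np.ones(n), r])
    XtW = X.T * w_norm
    A = XtW @ X
    beta = np.linalg.solve(A, XtW @ y)
    u = y - X @ beta
    k = 2
    if cluster:
        codes = np.unique(np.asarray(cluster_ids), return_inverse=True)[1]
        g = codes.max() + 1
        s = np.zeros((g, k))
        wu = w_norm * u
        np.add.at(s, codes, X * wu[:, None])
        meat = s.T @ s
        corr = (g / (g - 1.0)) * ((n - 1.0) / (n - k))
    else:
        wu2 = (w_norm * u) ** 2
        meat = (X * wu2[:, None]).T @ X
        corr = n / (n - k)
    Ainv = np.linalg.inv(A)
    V = corr * (Ainv @ meat @ Ainv)
    return float(beta[1]), float(math.sqrt(max(V[1, 1], 0.0)))


def index_inference(h, ranks, weights, psu_ids, cluster: bool = True) -> ConcentrationResult:
    """Corrected concentration indices with standard errors.

    Point estimates use the covariance formulas; SEs come from the
    convenient-regression slope. With ``cluster=True`` (default) the
    variance is cluster-robust by PSU; with a single PSU the computation
    falls back to heteroskedasticity-robust (HC1) SEs with a warning.
    """
    h = _check_binary(h)
    r = np.asarray(ranks, dtype=float)
    w = _as_weights(weights, h.size)
    psu = np.asarray(psu_ids)
    if psu.shape != h.shape:
        raise ValidationError("psu_ids must align with the outcome vector")
    mu = float(w @ h)
    if mu <= 0.0 or mu >= 1.0:
        raise DegenerateOutcomeError(
            f"index inference undefined for degenerate outcome (mu={mu:g})"
        )
    c = 2.0 / mu * _weighted_cov(h, r, w)
    wag = wagstaff_index(c, mu)
    err = erreygers_index(c, mu)

    n_clusters = int(np.unique(psu).size)
    use_cluster = cluster and n_clusters >= 2
    if cluster and n_clusters < 2:
        logger.warning(
            "single PSU: falling back to heteroskedasticity-robust standard errors"
        )
    var_r = _weighted_cov(r, r, w)
    # convenient regression: slope of y on rank equals the target index
    y_w = (2.0 * var_r / (mu * (1.0 - mu))) * h
    y_e = (8.0 * var_r) * h
    slope_w, se_w = _wls_slope_sandwich(y_w, r, w, psu, use_cluster)
    slope_e, se_e = _wls_slope_sandwich(y_e, r, w, psu, use_cluster)
    # the regression slopes reproduce the covariance-formula estimates
    # exactly in exact arithmetic; keep the covariance values as the
    # point estimates and use the regressions only for the variance.
    del slope_w, slope_e
    z = 1.959963984540054  # Phi^{-1}(0.975)
    return ConcentrationResult(
        mu=mu,
        ci_raw=c,
        wagstaff=wag,
        erreygers=err,
        se_w=se_w,
        se_e=se_e,
        lower_w=wag - z * se_w,
        upper_w=wag + z * se_w,
        lower_e=err - z * se_e,
        upper_e=err + z * se_e,
        n=int(h.size),
        n_clusters=n_clusters if use_cluster else 1,
    )


def theil_decompose(values, groups, weights=None) -> TheilDecomposition:
    """Theil-T (GE(1)) index with exact within/between decomposition.

    Parameters
    ----------
    values : nonnegative unit-level quantities (e.g., subnational coverage
        estimates); at least one must be positive. Zeros contribute
        0 * ln(0) = 0.
    groups : group label per unit (e.g., country).
    weights : optional positive unit weights (e.g., sample sizes). Default
        is unweighted, each unit counting equally.

    Returns
    -------
    TheilDecomposition with ``total == within + between`` exactly:

        total   = sum_i s_i (x_i/mu) ln(x_i/mu)
        within  = sum_g S_g (mu_g/mu) T_g
        between = sum_g S_g (mu_g/mu) ln(mu_g/mu)

    where s_i are normalized weights, S_g group weight shares, mu and mu_g
    the overall and group weighted means, and T_g the within-group Theil.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("values must be a nonempty one-dimensional array")
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ValidationError("values must be finite and nonnegative")
    if not np.any(x > 0):
        raise ValidationError("Theil index undefined: all values are zero")
    g = np.asarray(groups)
    if g.shape != x.shape:
        raise ValidationError("groups must align with values")
    if weights is None:
        s = np.full(x.size, 1.0 / x.size)
    else:
        s = _as_weights(weights, x.size)

    mu = float(s @ x)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0, (x / mu) * np.log(x / mu), 0.0)
    total = float(s @ term)

    codes, inv = np.unique(g, return_inverse=True)
    within = 0.0
    between = 0.0
    for gi in range(codes.size):
        mask = inv == gi
        sg = float(s[mask].sum())
        mug = float(s[mask] @ x[mask]) / sg
        if mug > 0:
            xg = x[mask]
            sgn = s[mask] / sg
            with np.errstate(divide="ignore", invalid="ignore"):
                tg = float(
                    sgn @ np.where(xg > 0, (xg / mug) * np.log(xg / mug), 0.0)
                )
            within += sg * (mug / mu) * tg
            between += sg * (mug / mu) * math.log(mug / mu)
        # a group whose mean is zero contributes nothing to either part
    return TheilDecomposition(total=total, within=within, between=between)
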