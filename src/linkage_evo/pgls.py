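"""Phylogenetic generalized least squares with Pagel's lambda.

Mechanical sensitivity is quantified as the strength of the PGLS
relationship between kinematic transmission (response) and each
size-corrected, log-transformed mobile-link length (predictor).  The
regression model is

    y = X b + e,    e ~ N(0, sigma^2 * C(lambda))

where ``C`` is the Brownian-motion phylogenetic covariance and
``C(lambda)`` multiplies its off-diagonal entries by Pagel's lambda.
lambda is estimated by maximising the profile log-likelihood over [0, 1]
simultaneously with the regression coefficients (REML is not used).

Conventions: r^2 is ``1 - RSS/TSS`` computed in the lambda-whitened space
against the GLS intercept-only model; AIC counts the residual variance
and lambda as estimated parameters (k = p + 2 for p coefficients);
p-values are two-sided t tests on the residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .errors import ConvergenceFailure, SingularDesign
from .phylo import Phylogeny, TraitTable, lambda_transform

__all__ = ["PGLSFit", "pgls_fit", "sensitivity_scan", "MOBILE_LINKS"]

MOBILE_LINKS = ("input", "output", "coupler")


@dataclass(frozen=True)
class PGLSFit:
    """Result of one PGLS regression."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    r_squared: float
    aic: float
    log_likelihood: float
    lambda_ml: float
    n: int
    df_residual: int
    names: tuple[str, ...] = field(default=())

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])


def _gls_profile(y: np.ndarray, X: np.ndarray, C: np.ndarray, lam: float):
    """GLS estimates and profile log-likelihood at a fixed lambda.

    Returns (beta, rss, tss, loglik, XtVinvX_inv) with sigma^2 profiled out
    at its ML value RSS/n.
    """
    n = y.shape[0]
    V = lambda_transform(C, lam)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise SingularDesign(f"covariance singular at lambda={lam:g}") from exc
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise SingularDesign("predictor matrix is rank deficient")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    # intercept-only GLS fit for the total sum of squares
    ones_w = linalg.solve_triangular(L, np.ones(n), lower=True)
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float(np.sum((yw - mu * ones_w) ** 2))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    sigma2_ml = rss / n
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet + n)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    return beta, rss, tss, loglik, xtx_inv


def pgls_fit(
    y: np.ndarray,
    X: np.ndarray,
    tree: Phylogeny | np.ndarray,
    lam: float | str = "ML",
    names: tuple[str, ...] | None = None,
    add_intercept: bool = True,
) -> PGLSFit:
    """Fit ``y ~ X`` by GLS under the lambda-scaled phylogenetic covariance.

    Parameters
    ----------
    y, X
        Response vector and predictor matrix, rows in tip order.
    tree
        A :class:`Phylogeny` or a precomputed covariance matrix.
    lam
        ``"ML"`` to maximise the profile likelihood over [0, 1], or a
        fixed value in [0, 1].
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n = y.shape[0]
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        if names is not None:
            names = ("intercept", *names)
    if names is None:
        names = ("intercept", *[f"x{i}" for i in range(1, X.shape[1])]) if add_intercept \
            else tuple(f"x{i}" for i in range(X.shape[1]))
    p = X.shape[1]
    if n <= p + 1:
        raise SingularDesign(f"need n > p + 1 (n={n}, p={p})")
    C = tree.vcv() if isinstance(tree, Phylogeny) else np.asarray(tree, dtype=float)

    if lam == "ML":
        def neg_profile(l: float) -> float:
            return -_gls_profile(y, X, C, l)[3]

        res = optimize.minimize_scalar(
            neg_profile, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:
            raise ConvergenceFailure("profile-likelihood optimisation over lambda failed")
        # the bounded optimiser can miss boundary optima; compare explicitly
        candidates = [(neg_profile(0.0), 0.0), (neg_profile(1.0), 1.0),
                      (res.fun, float(res.x))]
        lam_hat = min(candidates)[1]
    else:
        lam_hat = float(lam)

    beta, rss, tss, loglik, xtx_inv = _gls_profile(y, X, C, lam_hat)
    df_resid = n - p
    sigma2_hat = rss / df_resid
    se = np.sqrt(sigma2_hat * np.diag(xtx_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    k = p + 2  # coefficients + residual variance + lambda
    return PGLSFit(
        coefficients=beta,
        std_errors=se,
        t_stats=tvals,
        p_values=pvals,
        r_squared=float(r2),
        aic=float(2.0 * k - 2.0 * loglik),
        log_likelihood=float(loglik),
        lambda_ml=float(lam_hat),
        n=n,
        df_residual=df_resid,
        names=tuple(names),
    )


def sensitivity_scan(
    table: TraitTable,
    tree: Phylogeny,
    response: str = "kt",
    links: tuple[str, ...] = MOBILE_LINKS,
    lam: float | str = "ML",
    log_response: bool = True,
    multiple: bool = False,
) -> dict[str, PGLSFit]:
    """One PGLS per mobile link: KT against a size-corrected link length.

    Expects *table* rows aligned to *tree* tips, with a ``fixed`` column
    (raw lengths) and raw mobile-link columns; mobile links are divided by
    the fixed link and log-transformed before fitting, as is the response.
    Returns fits keyed by link name (plus ``"multiple"`` when a joint
    multiple regression is requested); the link with the highest r^2
    identifies the system's mechanical sensitivity.
    """
    fixed = table.values(["fixed"]).ravel()
    y = table.values([response]).ravel()
    if log_response:
        y = np.log(y)
    C = tree.vcv()
    fits: dict[str, PGLSFit] = {}
    predictors = {}
    for link in links:
        x = np.log(table.values([link]).ravel() / fixed)
        predictors[link] = x
        fits[link] = pgls_fit(y, x[:, None], C, lam=lam, names=(link,))
    if multiple:
        Xall = np.column_stack([predictors[l] for l in links])
        fits["multiple"] = pgls_fit(y, Xall, C, lam=lam, names=tuple(links))
    return fits


def rank_links(fits: dict[str, PGLSFit]) -> list[str]:
    """Links ordered from most to least mechanically sensitive (by r^2)."""
    single = {k: v for k, v in fits.items() if k != "multiple"}
    return sorted(single, key=lambda k: single[k].r_squared, reverse=True)
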