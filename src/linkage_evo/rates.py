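"""Brownian-motion evolutionary rates (tempo) and likelihood-ratio tests.

Each log-scale trait is modelled as an independent Brownian motion on the
phylogeny: the tip values are multivariate normal with covariance
``sigma2_k * C`` (plus a diagonal of within-species measurement-error
variances when supplied) around a phylogenetic mean estimated by GLS.
Evolutionary tempo is compared by fitting

* an equal-rate model, one sigma^2 shared by all traits, and
* a free-rate model, one sigma^2 per trait,

and contrasting them with a likelihood-ratio test (chi^2 with
``n_traits - 1`` degrees of freedom for the joint test; every pairwise
combination of traits is also tested at 1 df).  95% confidence intervals
come from the square-root diagonal of the inverse Hessian of the negative
log-likelihood, evaluated on the log-sigma^2 scale and back-transformed by
the delta method; they are reported as symmetric normal intervals on the
sigma^2 scale, truncated below at zero.

Because traits are log-transformed lengths, the rates are per-unit-time
variances of proportional change and are directly comparable across
traits of different absolute size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .errors import ConvergenceFailure, SingularCovariance
from .phylo import Phylogeny, TraitTable

__all__ = [
    "RateComparison",
    "bm_loglik",
    "compare_rates",
    "rate_with_measurement_error",
]


@dataclass(frozen=True)
class RateComparison:
    """Per-trait sigma^2 estimates plus equal-vs-free model comparison."""

    traits: tuple[str, ...]
    sigma2: np.ndarray
    ci95: np.ndarray  # shape (k, 2): lower, upper
    std_errors: np.ndarray
    sigma2_equal: float
    loglik_equal: float
    loglik_free: float
    lrt_stat: float
    df: int
    p_value: float
    pairwise: dict[tuple[str, str], dict]

    def to_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "sigma2": {t: float(s) for t, s in zip(self.traits, self.sigma2)},
            "ci95": {t: [float(l), float(u)] for t, (l, u) in zip(self.traits, self.ci95)},
            "sigma2_equal": float(self.sigma2_equal),
            "loglik_equal": float(self.loglik_equal),
            "loglik_free": float(self.loglik_free),
            "lrt": float(self.lrt_stat),
            "df": int(self.df),
            "p": float(self.p_value),
            "pairwise": {
                f"{a}|{b}": {k: (float(v) if np.isscalar(v) else v) for k, v in d.items()}
                for (a, b), d in self.pairwise.items()
            },
        }


class _BMLikelihood:
    """Cached machinery for the per-trait BM log-likelihood.

    When no measurement error is present the covariance is
    ``sigma2 * C`` for every trait, so the data can be whitened once by
    the Cholesky factor of ``C`` and each likelihood evaluation is O(n).
    With measurement error the covariance ``sigma2*C + diag(me)`` must be
    refactorised per evaluation.
    """

    def __init__(self, Y: np.ndarray, C: np.ndarray, me: np.ndarray | None):
        self.Y = Y  # (n, k)
        self.C = C
        self.me = me  # (n, k) or None
        self.n, self.k = Y.shape
        try:
            self.L = linalg.cholesky(C, lower=True)
        except linalg.LinAlgError as exc:
            raise SingularCovariance("phylogenetic covariance not positive definite") from exc
        self.logdetC = 2.0 * float(np.sum(np.log(np.diag(self.L))))
        self.Yw = linalg.solve_triangular(self.L, Y, lower=True)
        self.ones_w = linalg.solve_triangular(self.L, np.ones(self.n), lower=True)
        # GLS residual quadratic forms under covariance C (no me)
        mu = (self.ones_w @ self.Yw) / (self.ones_w @ self.ones_w)
        resid = self.Yw - np.outer(self.ones_w, mu)
        self.Q = np.sum(resid * resid, axis=0)  # (k,)

    def analytic_sigma2(self) -> np.ndarray:
        """Closed-form per-trait ML rates when measurement error is absent."""
        return self.Q / self.n

    def loglik_trait(self, j: int, sigma2: float) -> float:
        if sigma2 <= 0 or not np.isfinite(sigma2):
            return -np.inf
        n = self.n
        if self.me is None:
            logdet = n * np.log(sigma2) + self.logdetC
            quad = self.Q[j] / sigma2
        else:
            V = sigma2 * self.C + np.diag(self.me[:, j])
            try:
                L = linalg.cholesky(V, lower=True)
            except linalg.LinAlgError:
                return -np.inf
            yw = linalg.solve_triangular(L, self.Y[:, j], lower=True)
            ow = linalg.solve_triangular(L, np.ones(n), lower=True)
            mu = float(ow @ yw) / float(ow @ ow)
            r = yw - mu * ow
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            quad = float(r @ r)
        return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)

    def loglik(self, sigma2s: np.ndarray) -> float:
        return float(sum(self.loglik_trait(j, sigma2s[j]) for j in range(self.k)))


def bm_loglik(
    traits: TraitTable | np.ndarray,
    tree: Phylogeny | np.ndarray,
    rates,
    me: np.ndarray | None = None,
    columns=None,
) -> float:
    """Joint log-likelihood of independent BM traits at given rates.

    ``rates`` may be a scalar (shared by all traits) or one value per
    trait.  ``me`` is an optional (n, k) array of per-species
    measurement-error variances added to each trait's covariance diagonal.
    The phylogenetic mean of each trait is profiled out by GLS.
    """
    Y = _trait_matrix(traits, columns)
    C = tree.vcv() if isinstance(tree, Phylogeny) else np.asarray(tree, dtype=float)
    k = Y.shape[1]
    sigma2s = np.broadcast_to(np.atleast_1d(np.asarray(rates, dtype=float)), (k,))
    lik = _BMLikelihood(Y, C, _me_matrix(me, Y.shape))
    return lik.loglik(np.asarray(sigma2s, dtype=float))


def _trait_matrix(traits, columns) -> np.ndarray:
    if isinstance(traits, TraitTable):
        cols = list(columns) if columns is not None else traits.trait_columns
        return traits.values(cols)
    Y = np.asarray(traits, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def _me_matrix(me, shape):
    if me is None:
        return None
    me = np.asarray(me, dtype=float)
    if me.ndim == 1:
        me = me[:, None]
    me = np.broadcast_to(me, shape).copy()
    if np.any(me < 0):
        raise ValueError("measurement-error variances must be non-negative")
    return me


def _fit_free(lik: _BMLikelihood) -> tuple[np.ndarray, float]:
    """ML rates under the free model, one sigma^2 per trait."""
    init = np.maximum(lik.analytic_sigma2(), 1e-12)
    if lik.me is None:
        # whitened likelihood is exactly maximised by the analytic rates
        return init, lik.loglik(init)
    est = np.empty(lik.k)
    for j in range(lik.k):
        res = optimize.minimize_scalar(
            lambda ls, j=j: -lik.loglik_trait(j, np.exp(ls)),
            bracket=(np.log(init[j]) - 1.0, np.log(init[j]) + 1.0),
            method="brent", options={"xtol": 1e-10},
        )
        if not np.isfinite(res.fun):
            raise ConvergenceFailure(f"free-rate fit failed for trait {j}")
        est[j] = np.exp(res.x)
    return est, lik.loglik(est)


def _fit_equal(lik: _BMLikelihood) -> tuple[float, float]:
    """ML common rate under the equal-rate constraint."""
    init = float(np.mean(lik.analytic_sigma2()))
    if lik.me is None:
        s2 = float(np.sum(lik.Q) / (lik.n * lik.k))
        return s2, lik.loglik(np.full(lik.k, s2))
    res = optimize.minimize_scalar(
        lambda ls: -lik.loglik(np.full(lik.k, np.exp(ls))),
        bracket=(np.log(init) - 1.0, np.log(init) + 1.0),
        method="brent", options={"xtol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceFailure("equal-rate fit failed")
    s2 = float(np.exp(res.x))
    return s2, lik.loglik(np.full(lik.k, s2))


def _hessian_se(lik: _BMLikelihood, sigma2s: np.ndarray) -> np.ndarray:
    """Delta-method SEs of sigma2 from the log-scale observed information.

    Traits are independent, so the Hessian is diagonal; each second
    derivative is taken by central finite differences on log sigma^2.
    """
    se = np.empty(lik.k)
    h = 1e-4
    for j in range(lik.k):
        ls = np.log(sigma2s[j])
        f0 = lik.loglik_trait(j, sigma2s[j])
        fp = lik.loglik_trait(j, np.exp(ls + h))
        fm = lik.loglik_trait(j, np.exp(ls - h))
        d2 = (fp - 2.0 * f0 + fm) / (h * h)
        info = max(-d2, 1e-300)
        se[j] = sigma2s[j] / np.sqrt(info)  # delta method: d sigma2/d log sigma2 = sigma2
    return se


def compare_rates(
    traits: TraitTable | np.ndarray,
    tree: Phylogeny | np.ndarray,
    me: np.ndarray | None = None,
    columns=None,
) -> RateComparison:
    """Equal-rate vs free-rate BM model comparison across >= 2 traits."""
    Y = _trait_matrix(traits, columns)
    if Y.shape[1] < 2:
        raise ValueError("rate comparison requires at least two traits")
    names = tuple(columns) if columns is not None else (
        tuple(traits.trait_columns) if isinstance(traits, TraitTable)
        else tuple(f"trait{i}" for i in range(Y.shape[1]))
    )
    names = names[: Y.shape[1]]
    C = tree.vcv() if isinstance(tree, Phylogeny) else np.asarray(tree, dtype=float)
    me_arr = _me_matrix(me, Y.shape)
    lik = _BMLikelihood(Y, C, me_arr)

    sigma2_free, ll_free = _fit_free(lik)
    sigma2_eq, ll_eq = _fit_equal(lik)
    lrt = max(2.0 * (ll_free - ll_eq), 0.0)
    df = Y.shape[1] - 1
    p = float(stats.chi2.sf(lrt, df))
    se = _hessian_se(lik, sigma2_free)
    ci = np.column_stack([
        np.maximum(sigma2_free - 1.96 * se, 0.0),
        sigma2_free + 1.96 * se,
    ])

    pairwise: dict[tuple[str, str], dict] = {}
    for a, b in itertools.combinations(range(Y.shape[1]), 2):
        sub = _BMLikelihood(Y[:, [a, b]], C, None if me_arr is None else me_arr[:, [a, b]])
        s2f, llf = _fit_free(sub)
        s2e, lle = _fit_equal(sub)
        stat = max(2.0 * (llf - lle), 0.0)
        pairwise[(names[a], names[b])] = {
            "lrt": stat,
            "df": 1,
            "p": float(stats.chi2.sf(stat, 1)),
            "ratio": float(s2f[1] / s2f[0]),
        }

    return RateComparison(
        traits=names,
        sigma2=sigma2_free,
        ci95=ci,
        std_errors=se,
        sigma2_equal=sigma2_eq,
        loglik_equal=ll_eq,
        loglik_free=ll_free,
        lrt_stat=lrt,
        df=df,
        p_value=p,
        pairwise=pairwise,
    )


def rate_with_measurement_error(
    traits: TraitTable | np.ndarray,
    tree: Phylogeny | np.ndarray,
    me_variance,
    columns=None,
) -> RateComparison:
    """Rate comparison absorbing within-species measurement error.

    Identical to :func:`compare_rates` with ``diag(me)`` added to each
    trait's covariance; supplying honest measurement-error variances
    prevents per-species sampling noise from inflating sigma^2.
    """
    if me_variance is None:
        raise ValueError("me_variance is required; use compare_rates without it")
    return compare_rates(traits, tree, me=me_variance, columns=columns)
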