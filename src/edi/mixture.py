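"""Univariate Gaussian mixture fitting and BIC selection of the EDI score.

A tumor's regional diversity scores D = d_1..d_n are modelled as a
K-component univariate Gaussian mixture

    D ~ sum_k  w_k N(mu_k, sigma_k^2),

with unequal per-component variances.  The mixture is fitted by EM for each
K in a range (1..5 by default) and the Bayesian information criterion

    BIC(K) = -2 log L + (3K - 1) ln n

is minimised to choose K; ties break toward the smaller K.  The selected K
is the ecosystem diversity index (EDI): the number of distinct levels of
local diversity coexisting in the tumor.  Components are always reported in
ascending order of mean, so cluster k1 has the lowest diversity and kK the
highest.

The EM here is written directly for the 1-D case: restarts are cheap, the
variance floor is applied exactly (sigma_k^2 >= floor, guarding against
likelihood blow-up on coincident points), and results depend only on the
multiset of scores and the seed, not on input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm, pearsonr
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .diversity import DiversityProfile

_LOG_2PI = float(np.log(2.0 * np.pi))


class InfeasibleFitError(ValueError):
    """Requested more mixture components than data points."""


@dataclass
class MixtureFit:
    """A fitted K-component univariate Gaussian mixture.

    ``n_params`` is 3K - 1: K means, K variances, K - 1 free weights.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    seed: int | None = None

    @property
    def n_params(self) -> int:
        return 3 * self.k - 1

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / np.sqrt(self.variances)
        comp = (
            np.log(self.weights)
            - 0.5 * (z**2 + np.log(self.variances) + _LOG_2PI)
        )
        return logsumexp(comp, axis=-1)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / np.sqrt(self.variances)
        return norm.cdf(z) @ self.weights

    def responsibilities(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x[:, None] - self.means) / np.sqrt(self.variances)
        comp = (
            np.log(self.weights)
            - 0.5 * (z**2 + np.log(self.variances) + _LOG_2PI)
        )
        return np.exp(comp - logsumexp(comp, axis=1, keepdims=True))

    def predict(self, x) -> np.ndarray:
        """Maximum-posterior component label (0 = lowest-mean component)."""
        return np.argmax(self.responsibilities(np.asarray(x, float)), axis=1)


def _as_scores(d) -> np.ndarray:
    if isinstance(d, DiversityProfile):
        d = d.d
    d = np.asarray(d, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty diversity profile")
    return d


def _em_once(
    x: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    weights: np.ndarray,
    max_iter: int,
    tol: float,
    variance_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    n = x.size
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = (x[:, None] - means) / np.sqrt(variances)
        logcomp = (
            np.log(weights) - 0.5 * (z**2 + np.log(variances) + _LOG_2PI)
        )
        lognorm = logsumexp(logcomp, axis=1, keepdims=True)
        loglik = float(lognorm.sum())
        resp = np.exp(logcomp - lognorm)
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, variance_floor)
        if loglik - prev < tol and it > 1:
            converged = True
            break
        prev = loglik
    z = (x[:, None] - means) / np.sqrt(variances)
    logcomp = np.log(weights) - 0.5 * (z**2 + np.log(variances) + _LOG_2PI)
    loglik = float(logsumexp(logcomp, axis=1).sum())
    return means, variances, weights, loglik, converged, it


def fit_gmm(
    d,
    k: int,
    *,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    variance_floor: float = 1e-6,
    seed: int | None = 0,
) -> MixtureFit:
    """Fit a K-component univariate Gaussian mixture to diversity scores.

    The first EM run starts from quantile-spread means with equal weights;
    the remaining ``n_restarts - 1`` runs draw means uniformly from the
    data range.  The best run by log-likelihood wins.  ``k = 1`` is solved
    in closed form (sample mean and variance).  The result is a
    deterministic function of the multiset of scores and the seed.

    Raises
    ------
    InfeasibleFitError
        If ``k`` exceeds the number of scores.
    """
    x = np.sort(_as_scores(d))
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise InfeasibleFitError(f"cannot fit {k} components to {n} points")

    if k == 1:
        mu = float(x.mean())
        var = max(float(x.var()), variance_floor)
        loglik = float(
            -0.5 * n * (_LOG_2PI + np.log(var)) - ((x - mu) ** 2).sum() / (2 * var)
        )
        return MixtureFit(
            k=1,
            weights=np.array([1.0]),
            means=np.array([mu]),
            variances=np.array([var]),
            loglik=loglik,
            converged=True,
            n_iter=0,
            seed=seed,
        )

    var0 = max(float(x.var()), variance_floor)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            q = (np.arange(k) + 0.5) / k
            means = np.quantile(x, q)
        else:
            means = rng.uniform(x.min(), x.max(), size=k)
        variances = np.full(k, var0)
        weights = np.full(k, 1.0 / k)
        fitted = _em_once(
            x, means.copy(), variances, weights, max_iter, tol, variance_floor
        )
        if best is None or fitted[3] > best[3]:
            best = fitted
    means, variances, weights, loglik, converged, n_iter = best
    order = np.argsort(means)
    return MixtureFit(
        k=k,
        weights=weights[order],
        means=means[order],
        variances=variances[order],
        loglik=loglik,
        converged=bool(converged),
        n_iter=int(n_iter),
        seed=seed,
    )


def bic(fit: MixtureFit, n: int) -> float:
    """Bayesian information criterion ``-2 logL + (3K - 1) ln n``; lower wins."""
    if n <= 0:
        raise ValueError("n must be positive")
    return -2.0 * fit.loglik + fit.n_params * float(np.log(n))


def qq_diagnostic(fit: MixtureFit, d) -> float:
    """Goodness of fit: Pearson r between data and mixture quantiles.

    Theoretical quantiles of the fitted mixture are taken at plotting
    positions ``(i - 0.5)/n`` by monotone numerical inversion of the
    mixture CDF, and correlated with the sorted empirical scores.  Returns
    NaN when undefined (n < 3 or zero-variance data).
    """
    x = np.sort(_as_scores(d))
    n = x.size
    if n < 3 or np.ptp(x) == 0:
        return float("nan")
    probs = (np.arange(1, n + 1) - 0.5) / n
    sd = np.sqrt(fit.variances)
    lo = float((fit.means - 8 * sd).min())
    hi = float((fit.means + 8 * sd).max())
    # invert the monotone mixture CDF on a fine grid (affine-equivariant
    # because the grid itself is built from the component parameters)
    grid = np.linspace(lo, hi, 8192)
    cdf = fit.cdf(grid)
    theo = np.interp(probs, cdf, grid)
    if np.ptp(theo) == 0:
        return float("nan")
    return float(pearsonr(x, theo)[0])


class EDIMixture(ClusterMixin, BaseEstimator):
    """Mixture-model clustering of regional diversity scores with BIC.

    The fitted ``edi_`` attribute is the selected number of components,
    i.e. the ecosystem diversity index of the tumor whose regional Shannon
    scores were passed to :meth:`fit`.

    Parameters
    ----------
    k_max : int
        Largest component count tried (K ranges over 1..k_max; values with
        fewer data points than components are skipped).  The default 5
        avoids small EDI groups.
    n_restarts, max_iter, tol, variance_floor : EM controls
        See :func:`fit_gmm`.
    random_state : int
        Seed for the random restarts; fixing it makes fits bit-reproducible.

    Attributes
    ----------
    edi_ : int
        Selected K (min-BIC; ties to the smaller K).
    bic_table_ : dict[int, float]
        BIC per fitted K.
    fits_ : dict[int, MixtureFit]
        All per-K fits.
    mixture_ : MixtureFit
        The selected fit, components ascending by mean.
    labels_ : ndarray
        Maximum-posterior component per score, 0-based (0 = lowest mean).
    qq_correlation_ : float
        Q-Q goodness-of-fit correlation of the selected mixture.
    """

    def __init__(
        self,
        k_max: int = 5,
        n_restarts: int = 10,
        max_iter: int = 500,
        tol: float = 1e-8,
        variance_floor: float = 1e-6,
        random_state: int = 0,
        compute_qq: bool = True,
    ):
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.variance_floor = variance_floor
        self.random_state = random_state
        self.compute_qq = compute_qq

    def _fit_kwargs(self):
        return dict(
            n_restarts=self.n_restarts,
            max_iter=self.max_iter,
            tol=self.tol,
            variance_floor=self.variance_floor,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        """Fit mixtures for each feasible K and select by BIC.

        ``X`` may be a :class:`~edi.diversity.DiversityProfile`, a 1-D
        array of scores, or an (n, 1) array.
        """
        d = _as_scores(X)
        n = d.size
        self.fits_ = {}
        self.bic_table_ = {}
        for k in range(1, self.k_max + 1):
            if n < k:
                continue
            f = fit_gmm(d, k, **self._fit_kwargs())
            self.fits_[k] = f
            self.bic_table_[k] = bic(f, n)
        # ties break toward the smaller K: iterate in ascending K order
        self.edi_ = min(self.bic_table_, key=lambda k: (self.bic_table_[k], k))
        self.mixture_ = self.fits_[self.edi_]
        self.n_components_ = self.edi_
        self.labels_ = self.mixture_.predict(d)
        self.qq_correlation_ = (
            qq_diagnostic(self.mixture_, d) if self.compute_qq else float("nan")
        )
        return self

    def predict(self, X):
        """Maximum-posterior cluster labels under the selected mixture."""
        check_is_fitted(self, "mixture_")
        return self.mixture_.predict(_as_scores(X))


def select_k(d, k_max: int = 5, **kwargs) -> EDIMixture:
    """Fit all feasible K in 1..k_max and select by BIC (thin wrapper)."""
    return EDIMixture(k_max=k_max, **kwargs).fit(d)
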