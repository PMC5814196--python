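"""Negative-binomial mixed model with a random intercept, for paired counts.

The model for a count :math:`y_{ij}` from group (subject) :math:`i`,
observation :math:`j` is

.. math::

    y_{ij} \\mid u_i \\sim \\mathrm{NB2}(\\mu_{ij}, k), \\qquad
    \\log \\mu_{ij} = x_{ij}'\\beta + o_{ij} + u_i, \\qquad
    u_i \\sim N(0, \\sigma^2),

with NB2 variance :math:`\\mu + \\mu^2/k` (``k`` is the size / inverse
overdispersion), a known offset :math:`o_{ij}` (here the log total
protein-coding expression of the sample), and a normal random intercept
shared by a subject's tumor and normal samples.

The marginal likelihood integrates the random intercept out per group by
adaptive Gauss-Hermite quadrature: the integrand's mode is located by a
damped 1-D Newton iteration (vectorized over groups) and the Hermite nodes
are centred and scaled there, so few nodes (default 9) suffice even for
large :math:`\\sigma`.  All of :math:`\\beta`, :math:`\\log\\sigma` and
:math:`\\log k` are estimated jointly by maximizing this marginal
likelihood; standard errors come from the numerically differentiated
observed information.

The interface follows the statsmodels convention::

    model = NegativeBinomialMixedModel(y, X, groups=subject, offset=logtotal)
    res = model.fit()
    res.params, res.bse, res.pvalues, res.summary()

Groups must be balanced (the paired design has exactly one tumor and one
normal sample per subject), which the quadrature exploits for vectorization.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

__all__ = ["NegativeBinomialMixedModel", "NBMixedResults"]

_LOG_K_BOUNDS = (np.log(1e-4), np.log(1e4))
_LOG_SIGMA_BOUNDS = (np.log(1e-4), np.log(20.0))


def _nb2_logpmf(y: np.ndarray, mu: np.ndarray, k: float) -> np.ndarray:
    """NB2 log-pmf with mean ``mu`` and size ``k`` (variance mu + mu^2/k)."""
    return (gammaln(y + k) - gammaln(k) - gammaln(y + 1.0)
            + k * np.log(k) - (y + k) * np.log(mu + k) + y * np.log(mu))


class NegativeBinomialMixedModel:
    """NB2 regression with a normal random intercept per group.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Nonnegative integer counts.
    exog : array-like, shape (n, p)
        Fixed-effect design matrix (include the intercept column yourself).
    groups : array-like, shape (n,)
        Group labels; every group must contain the same number of
        observations (2 for a paired design).
    offset : array-like, shape (n,), optional
        Known log-scale exposure added to the linear predictor with
        coefficient one.
    exog_names : list of str, optional
        Column names for reporting; defaults to ``x0..x{p-1}``.
    """

    def __init__(self, endog, exog, groups, offset=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog have incompatible shapes")
        groups = np.asarray(groups)
        if groups.shape[0] != self.endog.shape[0]:
            raise ValueError("groups length must match endog")
        if offset is None:
            offset = np.zeros_like(self.endog)
        self.offset = np.asarray(offset, dtype=float)
        if not np.all(np.isfinite(self.offset)):
            raise ValueError("offsets must be finite")
        if np.any(self.endog < 0):
            raise ValueError("counts must be nonnegative")

        self.groups = groups
        labels, inv = np.unique(groups, return_inverse=True)
        counts = np.bincount(inv)
        if counts.min() != counts.max():
            raise ValueError(
                "unbalanced groups: every group must contribute the same "
                "number of observations (found sizes "
                f"{counts.min()}..{counts.max()})")
        self.n_groups = labels.shape[0]
        self.group_size = int(counts[0])
        order = np.argsort(inv, kind="stable")
        self._idx = order.reshape(self.n_groups, self.group_size)
        self._y = self.endog[self._idx]
        self.k_exog = self.exog.shape[1]
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(self.k_exog)]

    # ------------------------------------------------------------------
    def _eta(self, beta: np.ndarray) -> np.ndarray:
        lin = self.exog @ beta + self.offset
        return lin[self._idx]  # (G, m)

    def _laplace_mode(self, eta, k, sigma):
        """Vectorized damped Newton for the per-group integrand mode."""
        y = self._y
        u = np.zeros(self.n_groups)
        inv_s2 = 1.0 / sigma ** 2
        h = np.full(self.n_groups, -inv_s2)
        for _ in range(60):
            mu = np.exp(np.clip(eta + u[:, None], -700, 700))
            frac = mu / (mu + k)
            g = (y - (y + k) * frac).sum(axis=1) - u * inv_s2
            h = -((y + k) * k * mu / (mu + k) ** 2).sum(axis=1) - inv_s2
            step = g / h
            np.clip(step, -2.0, 2.0, out=step)
            u_new = u - step
            if np.max(np.abs(u_new - u)) < 1e-10:
                u = u_new
                break
            u = u_new
        return u, h

    def loglike(self, params: np.ndarray, n_quad: int = 9) -> float:
        """Marginal log-likelihood at ``params = (beta, log sigma, log k)``."""
        p = self.k_exog
        beta = params[:p]
        sigma = np.exp(params[p])
        k = np.exp(params[p + 1])
        eta = self._eta(beta)
        u_hat, h = self._laplace_mode(eta, k, sigma)
        s = 1.0 / np.sqrt(-h)
        x, w = np.polynomial.hermite.hermgauss(n_quad)
        u_nodes = u_hat[:, None] + np.sqrt(2.0) * s[:, None] * x  # (G, Q)
        mu = np.exp(np.clip(eta[:, :, None] + u_nodes[:, None, :], -700, 700))
        logf = _nb2_logpmf(self._y[:, :, None], mu, k).sum(axis=1)  # (G, Q)
        logf += norm.logpdf(u_nodes, scale=sigma)
        log_integral = (np.log(np.sqrt(2.0) * s)
                        + logsumexp(logf + x ** 2 + np.log(w), axis=1))
        return float(log_integral.sum())

    # ------------------------------------------------------------------
    def _start_params(self):
        y = self.endog
        z = np.log((y + 0.5) * np.exp(-self.offset))
        beta, *_ = np.linalg.lstsq(self.exog, z, rcond=None)
        mu = np.exp(np.clip(self.exog @ beta + self.offset, -700, 700))
        with np.errstate(divide="ignore", invalid="ignore"):
            excess = np.mean(((y - mu) ** 2 - mu) / np.maximum(mu, 1e-8) ** 2)
        k0 = 1.0 / max(excess, 1e-3)
        k0 = float(np.clip(k0, 1e-3, 1e3))
        return np.concatenate([beta, [np.log(0.3), np.log(k0)]])

    def fit(self, start_params=None, n_quad: int = 9, maxiter: int = 200,
            gtol: float = 1e-6, fixed_k: float | None = None,
            fixed_sigma: float | None = None) -> "NBMixedResults":
        """Maximize the marginal likelihood.

        ``fixed_k`` / ``fixed_sigma`` freeze the dispersion or the
        random-intercept SD at a given value instead of estimating them
        (useful for profiling and for symmetry checks).
        """
        p = self.k_exog
        full0 = self._start_params() if start_params is None else np.asarray(
            start_params, dtype=float)
        if fixed_sigma is not None:
            full0[p] = np.log(max(fixed_sigma, np.exp(_LOG_SIGMA_BOUNDS[0])))
        if fixed_k is not None:
            full0[p + 1] = np.log(fixed_k)
        free = np.ones(p + 2, dtype=bool)
        free[p] = fixed_sigma is None
        free[p + 1] = fixed_k is None

        template = full0.copy()

        def expand(theta):
            full = template.copy()
            full[free] = theta
            return full

        def nll(theta):
            full = expand(theta)
            full[p] = np.clip(full[p], *_LOG_SIGMA_BOUNDS)
            full[p + 1] = np.clip(full[p + 1], *_LOG_K_BOUNDS)
            try:
                return -self.loglike(full, n_quad=n_quad)
            except FloatingPointError:
                return np.inf

        bounds = [(None, None)] * p + [_LOG_SIGMA_BOUNDS, _LOG_K_BOUNDS]
        bounds = [b for b, f in zip(bounds, free) if f]
        with np.errstate(over="ignore", invalid="ignore"):
            opt = minimize(nll, full0[free], method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter, "ftol": 1e-10,
                                    "gtol": gtol})
            converged = bool(opt.success)
            if not converged:
                # L-BFGS-B line searches can fail on the sigma boundary even
                # at an optimum; a derivative-free polish settles it
                polish = minimize(nll, opt.x, method="Nelder-Mead",
                                  options={"maxiter": 400, "fatol": 1e-9,
                                           "xatol": 1e-7})
                improvement = opt.fun - polish.fun
                if polish.fun <= opt.fun + 1e-9:
                    opt = polish
                    # a successful polish, or one that found nothing better,
                    # confirms the L-BFGS-B point was already the optimum
                    converged = bool(polish.success) or improvement < 1e-6
        full_hat = expand(opt.x)
        full_hat[p] = np.clip(full_hat[p], *_LOG_SIGMA_BOUNDS)
        full_hat[p + 1] = np.clip(full_hat[p + 1], *_LOG_K_BOUNDS)

        cov = self._cov_params(full_hat, free, n_quad)
        return NBMixedResults(self, full_hat, cov, converged=converged,
                              llf=-float(opt.fun), n_quad=n_quad,
                              free_mask=free)

    def _cov_params(self, full_hat, free, n_quad):
        from statsmodels.tools.numdiff import approx_hess

        p = self.k_exog

        def nll_free(theta):
            full = full_hat.copy()
            full[free] = theta
            return -self.loglike(full, n_quad=n_quad)

        cov_full = np.full((p + 2, p + 2), np.nan)
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            try:
                hess = approx_hess(full_hat[free], nll_free)
                cov_free = np.linalg.pinv(hess)
            except Exception:
                return cov_full
        idx = np.flatnonzero(free)
        cov_full[np.ix_(idx, idx)] = cov_free
        return cov_full


class NBMixedResults:
    """Fit results: estimates, observed-information SEs, Wald tests."""

    def __init__(self, model, params_full, cov_params, converged, llf,
                 n_quad, free_mask):
        self.model = model
        p = model.k_exog
        self.params = params_full[:p]
        self.log_sigma = params_full[p]
        self.log_k = params_full[p + 1]
        self.sigma = float(np.exp(self.log_sigma))
        self.dispersion = float(np.exp(self.log_k))  # NB2 size k
        self._params_full = params_full
        self.cov_params = cov_params
        self.converged = converged
        self.llf = llf
        self.n_quad = n_quad
        self.free_mask = free_mask

    @property
    def bse(self) -> np.ndarray:
        var = np.diag(self.cov_params)[:self.model.k_exog]
        return np.sqrt(np.maximum(var, 0.0))

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values from the normal reference."""
        return 2.0 * norm.sf(np.abs(self.tvalues))

    def lr_test(self, drop: int) -> tuple[float, float]:
        """Likelihood-ratio test for dropping fixed-effect column ``drop``."""
        m = self.model
        keep = [j for j in range(m.k_exog) if j != drop]
        null = NegativeBinomialMixedModel(
            m.endog, m.exog[:, keep], m.groups, offset=m.offset,
            exog_names=[m.exog_names[j] for j in keep])
        res0 = null.fit(n_quad=self.n_quad)
        from scipy.stats import chi2
        stat = max(2.0 * (self.llf - res0.llf), 0.0)
        return stat, float(chi2.sf(stat, df=1))

    def summary(self) -> str:
        lines = [
            "Negative Binomial Mixed Model (random intercept, adaptive GHQ)",
            f"  groups: {self.model.n_groups}   obs/group: {self.model.group_size}"
            f"   quadrature nodes: {self.n_quad}",
            f"  log-likelihood: {self.llf:.4f}   converged: {self.converged}",
            f"  subject SD (sigma): {self.sigma:.4f}   NB size (k): {self.dispersion:.4f}",
            f"  {'term':<12}{'coef':>10}{'se':>10}{'z':>8}{'p':>10}",
        ]
        for name, b, se, z, pv in zip(self.model.exog_names, self.params,
                                      self.bse, self.tvalues, self.pvalues):
            lines.append(f"  {name:<12}{b:>10.4f}{se:>10.4f}{z:>8.2f}{pv:>10.3g}")
        return "\n".join(lines)
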