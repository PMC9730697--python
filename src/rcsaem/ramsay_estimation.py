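"""MAP estimation of Ramsay-curve spline coefficients by Newton-Raphson.

Given abilities sampled on the grid, the spline-coefficient log-posterior
(the "Ramsay-curve posterior", RCP) is

    l_R(eta) = sum_q n_q log g_q(eta) - (1/2)(eta - mu)' Sigma^{-1} (eta - mu),

where n_q counts the sampled abilities equal to grid point x_q.  Because the
basis spans the constant vector, the likelihood alone leaves a constant shift
in eta unidentified; the proper multivariate-normal prior resolves this, and
the fitted eta is re-centered to mean zero (the density is unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_spline import RamsayDensity, SplineBasis, ramsay_pdf

__all__ = ["EtaPrior", "GridCounts", "log_rcp", "rcp_derivatives", "fit_eta_map"]


@dataclass(frozen=True)
class EtaPrior:
    """MVN(mu, sigma) prior on the spline coefficients."""

    mu: np.ndarray
    sigma: np.ndarray

    @classmethod
    def diffuse(cls, m: int, tau: float = 10.0) -> "EtaPrior":
        """Default diffuse prior: mu = 0, sigma = tau^2 I."""
        return cls(mu=np.zeros(m), sigma=tau**2 * np.eye(m))

    def precision(self) -> np.ndarray:
        sig = np.asarray(self.sigma, dtype=float)
        if not np.allclose(sig, sig.T, atol=1e-12):
            raise ValueError("eta prior covariance must be symmetric")
        return np.linalg.inv(sig)


@dataclass(frozen=True)
class GridCounts:
    """Per-grid-point counts (possibly fractional after SA smoothing)."""

    n: np.ndarray

    @property
    def N(self) -> float:
        return float(self.n.sum())

    @classmethod
    def from_theta(cls, theta_idx: np.ndarray, Q: int) -> "GridCounts":
        return cls(n=np.bincount(theta_idx, minlength=Q).astype(float))


def log_rcp(eta: np.ndarray, counts: GridCounts, basis: SplineBasis,
            prior: EtaPrior) -> float:
    """Log Ramsay-curve posterior, up to an additive constant."""
    density = ramsay_pdf(basis, eta)
    loglik = float(counts.n @ density.log_g)  # exact in log space
    dev = np.asarray(eta, float) - prior.mu
    return loglik - 0.5 * float(dev @ prior.precision() @ dev)


def rcp_derivatives(eta: np.ndarray, counts: GridCounts, basis: SplineBasis,
                    prior: EtaPrior) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and Hessian of the log RCP.

    grad = B*'(n - N g) - Sigma^{-1}(eta - mu)
    hess = -N (B*' diag(g) B* - (B*'g)(B*'g)') - Sigma^{-1}
    """
    B = basis.matrix
    g = ramsay_pdf(basis, eta).g
    N = counts.N
    prec = prior.precision()
    grad = B.T @ (counts.n - N * g) - prec @ (np.asarray(eta, float) - prior.mu)
    Bg = B.T @ g
    hess = -N * ((B.T * g) @ B - np.outer(Bg, Bg)) - prec
    return grad, hess


def fit_eta_map(counts: GridCounts, basis: SplineBasis, prior: EtaPrior,
                init: np.ndarray | None = None, tol: float = 1e-6,
                max_inner: int = 50, recenter: bool = True) -> np.ndarray:
    """Newton-Raphson maximization of the log RCP with step-halving.

    Ascent is enforced by halving the Newton step (up to 20 times); if the
    negated Hessian is not positive definite a small ridge is added.
    Convergence: sup-norm change in eta below ``tol``.
    """
    m = basis.m
    eta = np.zeros(m) if init is None else np.asarray(init, dtype=float).copy()
    f = log_rcp(eta, counts, basis, prior)
    for _ in range(max_inner):
        grad, hess = rcp_derivatives(eta, counts, basis, prior)
        neg_hess = -hess
        try:
            step = np.linalg.solve(neg_hess, grad)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            ridge = 1e-8 * max(1.0, float(np.trace(neg_hess)) / m)
            try:
                step = np.linalg.solve(neg_hess + ridge * np.eye(m), grad)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "Newton step failed: negated RCP Hessian singular even "
                    "after ridge regularization"
                ) from exc
        scale = 1.0
        for _half in range(20):
            cand = eta + scale * step
            f_cand = log_rcp(cand, counts, basis, prior)
            if f_cand >= f - 1e-12:
                break
            scale *= 0.5
        else:
            break  # no ascent direction left; accept current point
        delta = float(np.max(np.abs(cand - eta)))
        eta, f = cand, f_cand
        if delta < tol:
            break
    if recenter:
        eta = eta - eta.mean()
    return eta


def density_from_counts(counts: GridCounts, basis: SplineBasis,
                        prior: EtaPrior, init: np.ndarray | None = None,
                        ) -> RamsayDensity:
    """Convenience: MAP-fit eta to grid counts and return the density."""
    eta = fit_eta_map(counts, basis, prior, init=init)
    return ramsay_pdf(basis, eta)
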