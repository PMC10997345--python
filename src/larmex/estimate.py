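"""ML/REML estimation for the stacked LARMEx model.

Each day contributes an independent marginal Gaussian block

    Y_i ~ N(X_i beta, V_i),    V_i = Z_i G Z_i' + sigma2 * I,

so the -2 log-likelihood (additive constants dropped) is

    l(beta, theta) = sum_i ln|V_i| + sum_i (Y_i - X_i beta)' V_i^{-1} (Y_i - X_i beta).

beta is profiled out by GLS at each covariance point; the remaining objective
is minimized over an unconstrained parameterization of (G, sigma2) by
quasi-Newton with numeric gradients.  REML adds ln|sum_i X_i' V_i^{-1} X_i|,
the textbook correction for the degrees of freedom spent on beta.  Realized
day effects are predicted afterwards by the BLUP
b_i = G Z_i' V_i^{-1} (Y_i - X_i beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .design import StackedData, StackedDay
from .model import G_STRUCTURES, build_cs_matrix

__all__ = ["CovParam", "FitResult", "marginal_cov", "gls_beta", "neg2_loglik",
           "fit", "blup"]

_BIG = 1e10           # optimizer-safe return for numerically singular V_i
_PSD_TOL = 1e-10


class CovParam:
    """Unconstrained parameterization of (G, sigma2) for one structure.

    diagonal
        theta = (s_1..s_q, log sigma2) with G = diag(s**2); the diagonal of
        the triangular factor is used directly, so components can hit the
        G = 0 boundary exactly.
    compound_symmetric
        theta = (log lam1, log lam2, log sigma2) where lam1 = v + (q-1)c and
        lam2 = v - c are the two distinct eigenvalues of a CS matrix — a
        bijection onto the positive-definite CS cone.
    block_cs_ar_exo_independent
        Independent CS blocks for the AR (k^2), exogenous (k), and constant
        (k) effects, each with its own (log lam1, log lam2) pair (single
        log-variance if the block has size 1), plus log sigma2.
    """

    def __init__(self, k: int, structure: str = "diagonal") -> None:
        if structure not in G_STRUCTURES:
            raise ValueError(f"unknown structure {structure!r}")
        self.k = k
        self.q = k * k + 2 * k
        self.structure = structure
        if structure == "block_cs_ar_exo_independent":
            self._blocks = [k * k, k, k]
        else:
            self._blocks = []

    @property
    def n_params(self) -> int:
        if self.structure == "diagonal":
            return self.q + 1
        if self.structure == "compound_symmetric":
            return 3
        return sum(1 if m == 1 else 2 for m in self._blocks) + 1

    @staticmethod
    def _cs_encode(block: np.ndarray) -> list[float]:
        m = block.shape[0]
        v = float(block[0, 0])
        if m == 1:
            if v <= 0:
                raise ValueError("CS block variance must be > 0 to encode")
            return [math.log(v)]
        c = float(block[0, 1])
        lam1, lam2 = v + (m - 1) * c, v - c
        if lam1 <= 0 or lam2 <= 0:
            raise ValueError("CS block must be positive definite to encode")
        return [math.log(lam1), math.log(lam2)]

    @staticmethod
    def _cs_decode(params: Sequence[float], m: int) -> np.ndarray:
        if m == 1:
            return np.array([[math.exp(params[0])]])
        lam1, lam2 = math.exp(params[0]), math.exp(params[1])
        v = (lam1 + (m - 1) * lam2) / m
        c = (lam1 - lam2) / m
        return build_cs_matrix(m, v, c)

    def encode(self, G: np.ndarray, sigma2: float) -> np.ndarray:
        """Map a PD (G, sigma2) to the unconstrained vector; exact inverse of
        :meth:`decode` for admissible inputs."""
        G = np.asarray(G, dtype=float)
        if sigma2 <= 0:
            raise ValueError("sigma2 must be > 0 to encode")
        if self.structure == "diagonal":
            d = np.diag(G)
            if np.any(d < 0):
                raise ValueError("diagonal G entries must be >= 0")
            theta = np.concatenate([np.sqrt(d), [math.log(sigma2)]])
            return theta
        if self.structure == "compound_symmetric":
            return np.array(self._cs_encode(G) + [math.log(sigma2)])
        params: list[float] = []
        pos = 0
        for m in self._blocks:
            params += self._cs_encode(G[pos:pos + m, pos:pos + m])
            pos += m
        params.append(math.log(sigma2))
        return np.array(params)

    def decode(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"theta has shape {theta.shape}, expected ({self.n_params},)")
        sigma2 = math.exp(theta[-1])
        if self.structure == "diagonal":
            return np.diag(theta[:-1] ** 2), sigma2
        if self.structure == "compound_symmetric":
            return self._cs_decode(theta[:2], self.q), sigma2
        G = np.zeros((self.q, self.q))
        pos_p, pos_m = 0, 0
        for m in self._blocks:
            npar = 1 if m == 1 else 2
            G[pos_m:pos_m + m, pos_m:pos_m + m] = self._cs_decode(
                theta[pos_p:pos_p + npar], m)
            pos_p += npar
            pos_m += m
        return G, sigma2


def marginal_cov(day: StackedDay, G: np.ndarray, sigma2: float) -> np.ndarray:
    """Marginal covariance V_i = Z_i G Z_i' + sigma2 * I of one day's block."""
    G = np.asarray(G, dtype=float)
    evals = np.linalg.eigvalsh(G)
    if evals.min(initial=0.0) < -_PSD_TOL * max(1.0, float(np.abs(evals).max(initial=1.0))):
        raise ValueError("G must be positive semi-definite")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    V = day.Z @ G @ day.Z.T
    V[np.diag_indices_from(V)] += sigma2
    return V


def _likelihood_pass(stacked: StackedData, G: np.ndarray, sigma2: float):
    """One sweep over days: logdet sum, A = sum X'V^-1 X, u = sum X'V^-1 Y,
    yvy = sum Y'V^-1 Y.  Raises LinAlgError if any V_i fails Cholesky."""
    q = stacked.q
    A = np.zeros((q, q))
    u = np.zeros(q)
    yvy = 0.0
    logdet = 0.0
    for day in stacked.days:
        V = day.Z @ G @ day.Z.T
        V[np.diag_indices_from(V)] += sigma2
        c, low = cho_factor(V, lower=True, check_finite=False)
        logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
        XY = np.column_stack([day.X, day.Y])
        W = cho_solve((c, low), XY, check_finite=False)   # V^-1 [X Y]
        AX = day.X.T @ W
        A += AX[:, :q]
        u += AX[:, q]
        yvy += float(day.Y @ W[:, q])
    return logdet, A, u, yvy


def _solve_beta(A: np.ndarray, u: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Solve the GLS normal equations; fall back to a generalized inverse."""
    try:
        c, low = cho_factor(A, lower=True, check_finite=False)
        cov = cho_solve((c, low), np.eye(A.shape[0]), check_finite=False)
        return cov @ u, cov, False
    except (LinAlgError, np.linalg.LinAlgError):
        cov = np.linalg.pinv(A, hermitian=True)
        return cov @ u, cov, True


def gls_beta(stacked: StackedData, G: np.ndarray, sigma2: float
             ) -> tuple[np.ndarray, np.ndarray]:
    """Generalized-least-squares fixed effects at known (G, sigma2).

    beta_hat = (sum X'V^-1 X)^-1 sum X'V^-1 Y and Cov(beta_hat) is that
    inverse; a pseudo-inverse is used when the sum is singular.
    """
    if all(not np.any(day.X) for day in stacked.days):
        raise ValueError("design matrix is identically zero")
    _, A, u, _ = _likelihood_pass(stacked, np.asarray(G, dtype=float), sigma2)
    beta, cov, _ = _solve_beta(A, u)
    return beta, cov


def neg2_loglik(theta: np.ndarray, stacked: StackedData, method: str = "ML",
                structure: str = "diagonal") -> float:
    """Profiled -2 log-likelihood (constants dropped) at a covariance point.

    beta is profiled out by GLS, so the value is
    sum ln|V_i| + sum r_i' V_i^-1 r_i, plus ln|sum X'V^-1 X| for REML.
    Numerically singular covariances return a large finite value (flagged via
    :func:`neg2_loglik.last_penalized`) so optimizers can step away.
    """
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    cov = CovParam(stacked.k, structure)
    neg2_loglik.last_penalized = False
    try:
        G, sigma2 = cov.decode(theta)
        logdet, A, u, yvy = _likelihood_pass(stacked, G, sigma2)
    except (LinAlgError, np.linalg.LinAlgError, OverflowError, ValueError):
        neg2_loglik.last_penalized = True
        return _BIG + float(np.sum(np.square(theta)))
    beta, _, _ = _solve_beta(A, u)
    quad = yvy - float(u @ beta)
    value = logdet + quad
    if method == "REML":
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            neg2_loglik.last_penalized = True
            return _BIG + float(np.sum(np.square(theta)))
        value += logdet_A
    if not np.isfinite(value):
        neg2_loglik.last_penalized = True
        return _BIG + float(np.sum(np.square(theta)))
    return float(value)


neg2_loglik.last_penalized = False


@dataclass
class FitResult:
    """Estimates, covariances, predictions, and convergence metadata."""

    beta_hat: np.ndarray             # (q,), design-column order
    G_hat: np.ndarray                # (q, q)
    sigma2_hat: float
    cov_beta: np.ndarray             # (q, q)
    blups: dict[int, np.ndarray]     # day_index -> (q,)
    neg2ll: float
    method: str
    structure: str
    converged: bool
    n_iter: int
    gradient_norm: float
    used_pinv: bool = False
    n_restarts: int = 0
    message: str = ""

    def blup_for(self, day_index: int) -> np.ndarray:
        if day_index not in self.blups:
            raise KeyError(f"day {day_index} was not part of the fit")
        return self.blups[day_index]

    def to_dict(self) -> dict:
        return {
            "beta_hat": self.beta_hat.tolist(),
            "G_hat": self.G_hat.tolist(),
            "sigma2_hat": self.sigma2_hat,
            "cov_beta": self.cov_beta.tolist(),
            "neg2ll": self.neg2ll,
            "method": self.method,
            "structure": self.structure,
            "convergence": {"converged": self.converged, "n_iter": self.n_iter,
                            "gradient_norm": self.gradient_norm,
                            "n_restarts": self.n_restarts,
                            "used_pinv": self.used_pinv,
                            "message": self.message},
            "blups": {str(i): b.tolist() for i, b in self.blups.items()},
        }


def blup(fit_state, day: StackedDay) -> np.ndarray:
    """Predict one day's realized random effects at the fitted parameters:
    b_i = G_hat Z_i' V_hat_i^-1 (Y_i - X_i beta_hat)."""
    G, sigma2, beta = fit_state.G_hat, fit_state.sigma2_hat, fit_state.beta_hat
    V = day.Z @ G @ day.Z.T
    V[np.diag_indices_from(V)] += sigma2
    c, low = cho_factor(V, lower=True, check_finite=False)
    resid = day.Y - day.X @ beta
    return G @ (day.Z.T @ cho_solve((c, low), resid, check_finite=False))


def _start_theta(stacked: StackedData, cov: CovParam) -> np.ndarray:
    """Heuristic start: OLS residual variance split between noise and G."""
    X = np.vstack([d.X for d in stacked.days])
    Y = np.concatenate([d.Y for d in stacked.days])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = max(1, len(Y) - X.shape[1])
    s2 = max(float(resid @ resid) / dof, 1e-6)
    g0 = 0.5 * s2
    sigma2_0 = 0.5 * s2
    if cov.structure == "diagonal":
        G0 = g0 * np.eye(cov.q)
    else:
        G0 = build_cs_matrix(cov.q, g0, 0.0)
        if cov.structure == "block_cs_ar_exo_independent":
            pass  # block-diagonal CS with zero covariance == g0 * I
    return cov.encode(G0, sigma2_0)


def fit(stacked: StackedData, structure: str = "diagonal", method: str = "REML",
        start: np.ndarray | None = None, max_restarts: int = 5,
        gtol: float = 1e-5, ftol: float = 1e-10, maxiter: int = 500,
        seed: int = 0) -> FitResult:
    """Estimate (beta, G, sigma2) and per-day BLUPs from stacked data.

    Quasi-Newton (L-BFGS-B, numeric gradients) on the unconstrained
    covariance parameterization, with up to ``max_restarts`` jittered restarts
    when the optimizer fails; never raises on non-convergence — the best point
    is returned with ``converged=False``.
    """
    method = method.upper()
    cov = CovParam(stacked.k, structure)
    theta0 = np.asarray(start, dtype=float) if start is not None else _start_theta(stacked, cov)

    def objective(theta: np.ndarray) -> float:
        return neg2_loglik(theta, stacked, method=method, structure=structure)

    rng = np.random.default_rng(seed)
    best = None
    n_restarts = 0
    for attempt in range(max_restarts + 1):
        t0 = theta0 if attempt == 0 else theta0 * (1 + 0.3 * rng.standard_normal(theta0.shape)) \
            + 0.1 * rng.standard_normal(theta0.shape)
        # floor on log sigma2 keeps V well-conditioned when data are
        # (near-)noiseless and the ML of sigma2 would run off to zero
        bounds = [(None, None)] * (cov.n_params - 1) + [(math.log(1e-12), None)]
        res = optimize.minimize(objective, t0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol})
        ok = bool(res.success) and res.fun < _BIG / 2
        if best is None or res.fun < best[0].fun:
            best = (res, ok)
        if ok:
            break
        n_restarts += 1
    res, converged = best
    G_hat, sigma2_hat = cov.decode(res.x)
    # clamp tiny negative eigenvalues arising from round-off (CS structures)
    evals, evecs = np.linalg.eigh(G_hat)
    if evals.min(initial=0.0) < 0:
        G_hat = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
    _, A, u, _ = _likelihood_pass(stacked, G_hat, sigma2_hat)
    beta_hat, cov_beta, used_pinv = _solve_beta(A, u)
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else float("nan")
    result = FitResult(
        beta_hat=beta_hat, G_hat=G_hat, sigma2_hat=sigma2_hat, cov_beta=cov_beta,
        blups={}, neg2ll=float(res.fun), method=method, structure=structure,
        converged=converged, n_iter=int(res.nit), gradient_norm=grad_norm,
        used_pinv=used_pinv, n_restarts=n_restarts, message=str(res.message))
    result.blups = {day.day_index: blup(result, day) for day in stacked.days}
    return result
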