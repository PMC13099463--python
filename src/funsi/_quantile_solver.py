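"""Interior-point solver for weighted pinball-loss (quantile) regression.

Solves  min_beta  sum_i w_i * rho_{tau_i}(y_i - x_i' beta)  where
rho_tau(r) = r * (tau - 1[r < 0]) is the check (pinball) loss, with a
per-row quantile level ``tau_i`` and nonnegative row weight ``w_i``.

The heterogeneous-tau/weight form is what makes this one routine serve
three purposes at once inside a single design matrix:

* data rows (weight 1, the curve's own tau),
* roughness-penalty rows (tau = 0.5 on second differences of spline
  coefficients, so each row contributes lambda * |D2 beta|),
* one-sided ordering rows (tau = 1 with a large weight M, an exact
  penalty for linear inequality constraints such as noncrossing of
  adjacent centile curves).

The algorithm is a Mehrotra predictor-corrector primal-dual interior
point method applied to the bounded-variable dual of the quantile
regression linear program (the approach of Portnoy & Koenker's
Frisch-Newton algorithm).  Each iteration costs one P x P Cholesky
factorisation plus sparse matrix-vector products, so problems with
hundreds of thousands of rows and a few hundred coefficients solve in
seconds.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve


class SolverError(RuntimeError):
    """Raised when the interior-point iteration fails to converge."""


def pinball_loss(residuals: np.ndarray, tau: float | np.ndarray) -> np.ndarray:
    """Elementwise check loss rho_tau(r) = r * (tau - 1[r < 0])."""
    r = np.asarray(residuals, dtype=float)
    return r * (tau - (r < 0.0))


def solve_weighted_quantile(
    X: sp.spmatrix | np.ndarray,
    y: np.ndarray,
    tau: np.ndarray,
    weights: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> np.ndarray:
    """Minimise the weighted pinball loss over beta.

    Parameters
    ----------
    X : (N, P) design matrix (sparse or dense).
    y : (N,) responses.
    tau : (N,) per-row quantile levels in [0, 1].
    weights : (N,) strictly positive row weights.
    tol : relative duality-gap tolerance.
    max_iter : iteration cap before declaring failure.

    Returns
    -------
    beta : (P,) coefficient vector.

    Notes
    -----
    Works on the dual LP  max y'a  s.t.  X'a = X'((1 - tau) * w),
    0 <= a <= w; the regression coefficients are the multipliers of the
    equality constraints.
    """
    X = sp.csr_matrix(X, dtype=float)
    y = np.asarray(y, dtype=float)
    tau = np.asarray(tau, dtype=float)
    u = np.asarray(weights, dtype=float)
    N, P = X.shape
    if not (len(y) == len(tau) == len(u) == N):
        raise ValueError("X, y, tau and weights must have matching lengths")
    if np.any(u <= 0):
        raise ValueError("weights must be strictly positive")
    if np.any((tau < 0) | (tau > 1)):
        raise ValueError("tau must lie in [0, 1]")

    Xt = X.T.tocsr()

    # Dual LP in minimisation form: min c'a, X'a = b, 0 <= a <= u.
    c = -y
    b = Xt @ ((1.0 - tau) * u)

    # Strictly interior start.
    a = np.clip((1.0 - tau) * u, 0.01 * u, 0.99 * u)
    s = u - a

    # Least-squares multiplier start; z - w splits the dual residual.
    M0 = (Xt @ X).toarray()
    M0[np.diag_indices_from(M0)] += 1e-10 * (1.0 + np.trace(M0) / P)
    lam = np.linalg.solve(M0, Xt @ c)
    r = c - X @ lam
    delta = 0.01 * (1.0 + np.abs(r).mean())
    z = np.maximum(r, 0.0) + delta
    w = np.maximum(-r, 0.0) + delta

    b_scale = 1.0 + np.abs(b).max(initial=0.0)
    mu0 = None

    for it in range(max_iter):
        r_p = b - Xt @ a
        r_d = c - X @ lam - z + w
        mu = (z @ a + w @ s) / (2.0 * N)
        if mu0 is None:
            mu0 = max(mu, 1e-300)

        feasible = np.abs(r_p).max(initial=0.0) < 1e-5 * b_scale
        if mu <= tol * mu0 and feasible:
            return -lam

        d = 1.0 / (z / a + w / s)

        def kkt_solve(t1: np.ndarray, t2: np.ndarray):
            r_vec = r_d - t1 / a + t2 / s
            rhs = r_p + Xt @ (d * r_vec)
            ADA = (Xt @ sp.diags(d) @ X).toarray()
            ADA[np.diag_indices_from(ADA)] += 1e-12 * (1.0 + np.trace(ADA) / P)
            try:
                cf = cho_factor(ADA, check_finite=False)
                dlam = cho_solve(cf, rhs, check_finite=False)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise SolverError("KKT system is singular") from exc
            da = d * (X @ dlam - r_vec)
            dz = (t1 - z * da) / a
            dw = (t2 + w * da) / s
            return dlam, da, dz, dw

        def step_len(v: np.ndarray, dv: np.ndarray) -> float:
            neg = dv < 0
            if not np.any(neg):
                return 1.0
            return min(1.0, float(np.min(-v[neg] / dv[neg])))

        # Affine (predictor) direction.
        dlam_a, da_a, dz_a, dw_a = kkt_solve(-a * z, -s * w)
        alpha_p = min(step_len(a, da_a), step_len(s, -da_a))
        alpha_d = min(step_len(z, dz_a), step_len(w, dw_a))
        mu_aff = (
            (z + alpha_d * dz_a) @ (a + alpha_p * da_a)
            + (w + alpha_d * dw_a) @ (s - alpha_p * da_a)
        ) / (2.0 * N)
        sigma = min(1.0, (mu_aff / mu) ** 3) if mu > 0 else 0.1

        # Corrector direction.
        t1 = sigma * mu - a * z - da_a * dz_a
        t2 = sigma * mu - s * w + da_a * dw_a
        dlam, da, dz, dw = kkt_solve(t1, t2)

        eta = 0.9995
        alpha_p = eta * min(step_len(a, da), step_len(s, -da))
        alpha_d = eta * min(step_len(z, dz), step_len(w, dw))
        alpha_p = min(alpha_p, 1.0)
        alpha_d = min(alpha_d, 1.0)
        if max(alpha_p, alpha_d) < 1e-10:
            # numerically pinned; accept if essentially converged
            if mu <= 1e-6 * mu0 and feasible:
                return -lam
            raise SolverError(f"stalled at mu={mu:.3e}")

        a += alpha_p * da
        s -= alpha_p * da
        lam += alpha_d * dlam
        z += alpha_d * dz
        w += alpha_d * dw

    raise SolverError(f"no convergence in {max_iter} iterations (mu={mu:.3e})")
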