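"""Independent oracles used by the tests: brute-force/active-set QP for the
l1-ball projection and a general-purpose constrained minimiser for the
spectral-norm prox.  These never call the package's own implementations of
the quantities they check."""

import numpy as np
from scipy.optimize import minimize


def l1_ball_qp_oracle_2d(v: np.ndarray, radius: float) -> np.ndarray:
    """Exact minimiser of ||u - v||^2 over the 2D l1 ball by active-set
    enumeration: the interior point, the four diamond faces and the four
    vertices are all candidate solutions."""
    v = np.asarray(v, dtype=float)
    candidates = []
    if np.abs(v).sum() <= radius:
        candidates.append(v)
    for s1 in (-1.0, 1.0):
        for s2 in (-1.0, 1.0):
            s = np.array([s1, s2])
            # projection onto the face hyperplane s . u = radius
            u = v - ((s @ v - radius) / 2.0) * s
            if s1 * u[0] >= -1e-12 and s2 * u[1] >= -1e-12:
                candidates.append(u)
    for vert in ([radius, 0.0], [-radius, 0.0], [0.0, radius], [0.0, -radius]):
        candidates.append(np.array(vert))
    costs = [np.sum((u - v) ** 2) for u in candidates]
    return candidates[int(np.argmin(costs))]


def spectral_prox_objective(M: np.ndarray, P: np.ndarray, rho: float) -> float:
    return 0.5 * float(np.sum((M - P) ** 2)) + rho * float(np.linalg.norm(M, 2))


def spectral_prox_slsqp_oracle(P: np.ndarray, rho: float, rng, n_starts: int = 5):
    """Multi-start SLSQP on the epigraph form:

        min_{M, t} 0.5*||M - P||_F^2 + rho*t   s.t.  t >= sigma_max(M), t >= 0

    with sigma_max expressed through the closed-form largest eigenvalue of
    the 2x2 Gram matrix M M^T.  Returns the best (M, objective) found.
    """

    def f(x):
        m = x[:6].reshape(2, 3)
        return 0.5 * np.sum((m - P) ** 2) + rho * x[6]

    def g(x):
        m = x[:6].reshape(2, 3)
        G = m @ m.T
        a, c, b = G[0, 0], G[1, 1], G[0, 1]
        lmax = 0.5 * ((a + c) + np.sqrt((a - c) ** 2 + 4.0 * b**2))
        return x[6] ** 2 - lmax

    best_x, best_f = None, np.inf
    for s in range(n_starts):
        scale = 1.0 if s == 0 else rng.uniform(0.0, 1.0)
        x0 = np.concatenate([P.ravel() * scale, [np.linalg.norm(P, 2) + 0.1]])
        res = minimize(
            f,
            x0,
            method="SLSQP",
            constraints=[{"type": "ineq", "fun": g}, {"type": "ineq", "fun": lambda x: x[6]}],
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    M = best_x[:6].reshape(2, 3)
    # Re-evaluate with the true spectral norm: SLSQP's epigraph variable can
    # undershoot sigma_max within its constraint tolerance.
    return M, spectral_prox_objective(M, P, rho)


def z_subproblem_gradient(Z, W, B_tilde, M_tilde, Y, mu, beta, D_diag):
    """Analytic gradient of the Z subproblem's objective, written from the
    augmented-Lagrangian terms directly (independent of the solver's
    closed-form update)."""
    grad = -(W - Z @ B_tilde) @ B_tilde.T - Y - mu * (M_tilde - Z)
    if beta != 0.0:
        grad = grad + beta * Z * (D_diag**2)[None, :]
    return grad
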