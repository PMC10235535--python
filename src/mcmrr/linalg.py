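"""Small linear-algebra primitives used by the ADMM shape solver.

All operators act on 2x3 motion-factor blocks ``M_i = c_i * R_i[:2, :]``
(a basis coefficient times the first two rows of a rotation matrix), so
the routines here are specialised to that shape where it matters.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "PI",
    "project_l1_ball",
    "prox_spectral_norm",
    "procrustes_2x3",
    "lift_rotation",
]

#: Orthographic projection matrix dropping the depth coordinate.
PI = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def project_l1_ball(v: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection of ``v`` onto the l1 ball of the given radius.

    Uses the sort-and-threshold algorithm: the projection of ``|v|`` onto
    the simplex-scaled ball is ``max(|v| - theta, 0)`` for the unique
    threshold ``theta >= 0``, with signs restored afterwards.

    Parameters
    ----------
    v
        Input vector (callers pass singular-value vectors, hence
        typically non-negative, but signed input is handled).
    radius
        Positive l1-ball radius.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("project_l1_ball: input has non-finite entries")
    if radius <= 0:
        raise ValueError("project_l1_ball: radius must be positive")
    a = np.abs(v)
    if a.sum() <= radius:
        return v.copy()
    # Duchi et al. sort-and-threshold; exact for any length.
    u = np.sort(a)[::-1]
    css = np.cumsum(u)
    idx = np.arange(1, a.size + 1)
    cond = u - (css - radius) / idx > 0
    rho = idx[cond][-1]
    theta = (css[rho - 1] - radius) / rho
    return np.sign(v) * np.maximum(a - theta, 0.0)


def _signed_svd(P: np.ndarray):
    """Thin SVD with a deterministic sign convention.

    The sign of each left singular vector is fixed so that its
    largest-magnitude entry is positive, making downstream prox output
    reproducible across LAPACK builds.
    """
    U, s, Vt = np.linalg.svd(P, full_matrices=False)
    for j in range(U.shape[1]):
        k = np.argmax(np.abs(U[:, j]))
        if U[k, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    return U, s, Vt


def prox_spectral_norm(P: np.ndarray, rho: float) -> np.ndarray:
    """Proximal operator of ``rho * ||M||_2`` (spectral norm) at ``P``.

    Returns ``argmin_M 0.5*||M - P||_F^2 + rho*sigma_max(M)``, computed by
    shrinking the singular values of ``P``:

        M = U diag(sigma - rho * Proj_l1(sigma / rho)) V^T

    where ``Proj_l1`` projects onto the unit l1 ball.  This is the Moreau
    decomposition of the spectral norm against its dual (nuclear) norm
    ball.
    """
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)):
        raise ValueError("prox_spectral_norm: input has non-finite entries")
    if rho < 0:
        raise ValueError("prox_spectral_norm: rho must be non-negative")
    if rho == 0:
        return P.copy()
    U, s, Vt = _signed_svd(P)
    shrunk = s - rho * project_l1_ball(s / rho, 1.0)
    return U @ np.diag(shrunk) @ Vt


def procrustes_2x3(T: np.ndarray) -> np.ndarray:
    """Closest row-orthonormal 2x3 matrix to ``T`` in the trace sense.

    Solves ``argmax_R trace(R T^T)`` subject to ``R R^T = I_2``; the
    maximiser is ``U V^T`` with ``U s V^T`` the thin SVD of ``T``.
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("procrustes_2x3: input has non-finite entries")
    U, s, Vt = np.linalg.svd(T, full_matrices=False)
    if s[0] <= 1e-300:
        raise ValueError("procrustes_2x3: rank-0 input is degenerate")
    return U @ Vt


def lift_rotation(R2: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Complete two orthonormal rotation rows to a full 3x3 rotation.

    The third row is the cross product of the first two, giving
    determinant +1 (the positive-depth lift of the weak-perspective
    camera).
    """
    R2 = np.asarray(R2, dtype=float)
    G = R2 @ R2.T
    if np.max(np.abs(G - np.eye(2))) > tol:
        raise ValueError("lift_rotation: rows are not orthonormal within tolerance")
    r3 = np.cross(R2[0], R2[1])
    return np.vstack([R2, r3])
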