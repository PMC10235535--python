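"""Shape-basis extraction from 3D training shapes.

Given F training shapes (3 x p landmark matrices), the module stacks them
into a 3p x F matrix A and fits the constrained dictionary model

    min_{N, X}  1/2 ||A - N X||_F^2 + lambda * (tau*||X||_1 + (1-tau)*||X||_2^2)
    s.t.        ||N_i||_F <= 1,  X_ij >= 0

by alternating projected gradient descent.  The elastic-net penalty
(l1 + squared l2) controls both the sparsity and the scale of the
coefficients; the learned dictionary columns are rearranged into K shape
bases B_i in R^{3 x p}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrainingMatrix",
    "ShapeBasisSet",
    "DictionaryState",
    "assemble_training_matrix",
    "elastic_net_objective",
    "learn_bases",
    "rearrange_N_to_B",
    "rearrange_B_to_N",
]


@dataclass(frozen=True)
class TrainingMatrix:
    """Stacked, per-frame-centered training set.

    ``A`` is 3p x F: column f holds frame f's landmarks flattened
    point-major as (x1, y1, z1, ..., xp, yp, zp) after subtracting the
    frame centroid.
    """

    A: np.ndarray
    p: int
    F: int

    def __post_init__(self):
        if self.A.shape != (3 * self.p, self.F):
            raise ValueError("TrainingMatrix: A must be 3p x F")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("TrainingMatrix: non-finite entries")


@dataclass(frozen=True)
class ShapeBasisSet:
    """K learned shape bases stacked vertically: B is 3K x p."""

    B: np.ndarray
    K: int
    p: int

    def __post_init__(self):
        if self.B.shape != (3 * self.K, self.p):
            raise ValueError("ShapeBasisSet: B must be 3K x p")
        if not np.all(np.isfinite(self.B)):
            raise ValueError("ShapeBasisSet: non-finite entries")

    def basis(self, i: int) -> np.ndarray:
        """The i-th 3 x p basis (0-based)."""
        return self.B[3 * i : 3 * i + 3, :]

    def __iter__(self):
        return (self.basis(i) for i in range(self.K))


@dataclass
class DictionaryState:
    """Mutable state of the alternating dictionary fit."""

    N: np.ndarray
    X: np.ndarray
    lambda_: float
    tau: float
    phi1: float
    phi2: float
    objective_trace: list[float] = field(default_factory=list)


def assemble_training_matrix(frames) -> TrainingMatrix:
    """Stack per-frame 3 x p shapes into the 3p x F training matrix.

    Each frame is centered (centroid subtracted) before flattening so
    that training shapes live in the same translation gauge as the
    centered 2D observations consumed by the solver.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if not frames:
        raise ValueError("assemble_training_matrix: need at least one frame")
    p = frames[0].shape[1]
    for k, f in enumerate(frames):
        if f.shape != (3, p):
            raise ValueError(
                f"assemble_training_matrix: frame {k} has shape {f.shape}, expected (3, {p})"
            )
    cols = []
    for f in frames:
        centered = f - f.mean(axis=1, keepdims=True)
        cols.append(centered.T.reshape(-1))  # point-major (x1,y1,z1,...)
    A = np.stack(cols, axis=1)
    return TrainingMatrix(A=A, p=p, F=len(frames))


def elastic_net_objective(
    A: np.ndarray, N: np.ndarray, X: np.ndarray, lambda_: float, tau: float
) -> float:
    """Value of the penalised reconstruction objective."""
    R = A - N @ X
    return 0.5 * float(np.sum(R * R)) + lambda_ * (
        tau * float(np.abs(X).sum()) + (1.0 - tau) * float(np.sum(X * X))
    )


def _project_columns_unit_ball(N: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(N, axis=0)
    scale = np.where(norms > 1.0, norms, 1.0)
    return N / scale


def learn_bases(
    training: TrainingMatrix,
    K: int,
    lambda_: float = 0.01,
    tau: float = 0.5,
    phi1: float = 1e-2,
    phi2: float = 1e-2,
    max_iter: int = 5000,
    tol: float = 1e-6,
    seed: int = 0,
    backtracking: bool = True,
) -> tuple[ShapeBasisSet, np.ndarray, DictionaryState]:
    """Fit the elastic-net dictionary and return the shape bases.

    Alternates a projected gradient step on X (clamped to the
    non-negative orthant) with one on N (columns projected onto the unit
    Frobenius ball).  With ``backtracking`` on, a step that increases the
    objective is retried with the step size halved, which keeps the
    objective trace non-increasing.

    Returns ``(bases, X, state)`` where ``bases.B`` is the 3K x p
    stacking of the rearranged dictionary columns.
    """
    A, p, F = training.A, training.p, training.F
    if not (1 <= K <= F):
        raise ValueError(f"learn_bases: require 1 <= K <= F, got K={K}, F={F}")
    if lambda_ < 0 or not (0.0 <= tau <= 1.0):
        raise ValueError("learn_bases: require lambda >= 0 and tau in [0, 1]")

    rng = np.random.default_rng(seed)
    cols = rng.choice(F, size=K, replace=False)
    N = A[:, cols].copy()
    norms = np.linalg.norm(N, axis=0)
    norms[norms == 0] = 1.0
    N /= norms
    X = np.maximum(N.T @ A, 0.0)

    state = DictionaryState(N=N, X=X, lambda_=lambda_, tau=tau, phi1=phi1, phi2=phi2)
    ones = np.ones_like(X)
    obj = elastic_net_objective(A, N, X, lambda_, tau)
    state.objective_trace.append(obj)
    increases = 0

    for _ in range(max_iter):
        # X step: gradient of the objective on the non-negative orthant.
        grad_X = -N.T @ (A - N @ X) + lambda_ * (tau * ones + 2.0 * (1.0 - tau) * X)
        step1 = phi1
        while True:
            X_new = np.maximum(X - step1 * grad_X, 0.0)
            obj_x = elastic_net_objective(A, N, X_new, lambda_, tau)
            if not backtracking or obj_x <= obj + 1e-15 or step1 < 1e-12:
                break
            step1 *= 0.5
        X = X_new

        # N step: data-term gradient, columns projected to the unit ball.
        grad_N = -(A - N @ X) @ X.T
        step2 = phi2
        while True:
            N_new = _project_columns_unit_ball(N - step2 * grad_N)
            obj_n = elastic_net_objective(A, N_new, X, lambda_, tau)
            if not backtracking or obj_n <= obj_x + 1e-15 or step2 < 1e-12:
                break
            step2 *= 0.5
        N = N_new

        new_obj = elastic_net_objective(A, N, X, lambda_, tau)
        state.objective_trace.append(new_obj)
        if new_obj > obj:
            increases += 1
            if increases >= 10:
                raise RuntimeError(
                    "learn_bases: objective increased for 10 consecutive iterations; "
                    "reduce the step sizes phi1/phi2"
                )
        else:
            increases = 0
        if obj > 0 and abs(obj - new_obj) / max(obj, 1e-300) < tol:
            obj = new_obj
            break
        obj = new_obj

    state.N, state.X = N, X
    return rearrange_N_to_B(N, p, K), X, state


def rearrange_N_to_B(N: np.ndarray, p: int, K: int) -> ShapeBasisSet:
    """Unstack dictionary columns (3p-vectors) into 3 x p bases.

    Column i of N holds basis i flattened point-major; basis i occupies
    rows 3i..3i+2 of B with ``B_i[:, j] = N[3j:3j+3, i]``.
    """
    N = np.asarray(N, dtype=float)
    if N.shape != (3 * p, K):
        raise ValueError(f"rearrange_N_to_B: N has shape {N.shape}, expected ({3 * p}, {K})")
    B = np.empty((3 * K, p))
    for i in range(K):
        B[3 * i : 3 * i + 3, :] = N[:, i].reshape(p, 3).T
    return ShapeBasisSet(B=B, K=K, p=p)


def rearrange_B_to_N(bases: ShapeBasisSet) -> np.ndarray:
    """Inverse of :func:`rearrange_N_to_B`."""
    N = np.empty((3 * bases.p, bases.K))
    for i in range(bases.K):
        N[:, i] = bases.basis(i).T.reshape(-1)
    return N
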