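"""Per-frame 3D shape and motion estimation from 2D landmarks.

Given learned shape bases B_i and one centered 2D observation W (2 x p),
the solver estimates the stacked motion factors M~ = [M_1, ..., M_K]
(each M_i = c_i * R_i[:2, :]) from the penalised least-square model

    min_{M~, Z}  1/2 ||W - Z B~||_F^2 + alpha * sum_i ||M_i||_2
                 + beta/2 * ||Z D||_F^2     s.t.  M~ = Z

where ||.||_2 is the spectral norm (a relaxed orthogonality constraint:
its prox shrinks singular values toward each other) and D is a diagonal
similarity penalty weighting each basis block by how far the observation
is from that basis's orthographic projection.  The constrained problem
is solved by ADMM on the augmented Lagrangian with an adaptive penalty
weight mu.

A rotation-synchronisation refinement then fits a single shared rotation
R_bar and per-basis coefficients c_i to the blocks of M~, and the 3D
shape is assembled as S = sum_i c_i * R * B_i with R the proper-rotation
lift of R_bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import ShapeBasisSet
from .linalg import PI, lift_rotation, procrustes_2x3, prox_spectral_norm

__all__ = [
    "Observation",
    "SimilarityWeights",
    "SolverConfig",
    "SolverState",
    "MotionEstimate",
    "ReconstructionResult",
    "VARIANTS",
    "center_observation",
    "similarity_weights",
    "update_M",
    "update_Z",
    "update_Y",
    "update_mu",
    "residuals",
    "admm_solve",
    "rotation_synchronize",
    "assemble_shape",
    "reconstruct",
    "reconstruct_sequence",
]

#: Solver variants: the full model, the plain convex-relaxation baseline
#: (no similarity penalty), and the two single-constraint ablations.
VARIANTS = ("mcmrr", "cra", "cra-en", "cra-sc")


@dataclass(frozen=True)
class Observation:
    """One frame's 2 x p landmark matrix, optionally centered."""

    W: np.ndarray
    centered: bool = False

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != 2:
            raise ValueError("Observation: W must be 2 x p")
        if not np.all(np.isfinite(W)):
            raise ValueError("Observation: non-finite entries")
        if self.centered and np.max(np.abs(W.mean(axis=1))) > 1e-9:
            raise ValueError("Observation: centered flag set but row means are not zero")
        object.__setattr__(self, "W", W)

    @property
    def p(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class SimilarityWeights:
    """Diagonal similarity penalty D = diag(d) kron I_3 (3K x 3K)."""

    d: np.ndarray
    gamma2: float

    @property
    def D(self) -> np.ndarray:
        return np.kron(np.diag(self.d), np.eye(3))

    @property
    def diag(self) -> np.ndarray:
        """The 3K-vector of diagonal entries (each d_i repeated 3x)."""
        return np.repeat(self.d, 3)


@dataclass
class SolverConfig:
    """Hyperparameters of the ADMM solver and refinement.

    alpha weights the spectral-norm (orthogonality-relaxation) term,
    beta the similarity penalty; gamma2 scales the similarity exponent
    (None = self-scaling median heuristic); eps is the convergence
    threshold on both relative residuals; ratio_threshold drives the
    adaptive mu doubling/halving rule.
    """

    alpha: float = 0.01
    beta: float = 0.001
    gamma2: float | None = None
    eps: float = 1e-4
    max_iter: int = 1000
    mu0: float = 1.0
    ratio_threshold: float = 10.0
    variant: str = "mcmrr"
    squared_distance: bool = True
    normalize_scale: bool = False

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("SolverConfig: eps must be positive")
        if self.max_iter < 1:
            raise ValueError("SolverConfig: max_iter must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("SolverConfig: alpha and beta must be non-negative")
        if self.mu0 <= 0:
            raise ValueError("SolverConfig: mu0 must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"SolverConfig: variant must be one of {VARIANTS}")

    @property
    def effective_beta(self) -> float:
        """The similarity weight actually used: 0 for the variants without it."""
        return 0.0 if self.variant in ("cra", "cra-en") else self.beta


@dataclass
class SolverState:
    """ADMM iterates and diagnostics."""

    M_tilde: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    mu: float
    delta1: float = np.inf
    delta2: float = np.inf
    iteration: int = 0
    converged: bool = False
    objective_trace: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class MotionEstimate:
    """Refined motion: coefficients c, shared rotation R_bar, raw factors."""

    c: np.ndarray
    R_bar: np.ndarray
    M_list: list[np.ndarray]


@dataclass
class ReconstructionResult:
    """Estimated 3 x p shape with motion and solver diagnostics."""

    S: np.ndarray
    motion: MotionEstimate
    state: SolverState
    translation: np.ndarray


def center_observation(W_raw: np.ndarray) -> tuple[Observation, np.ndarray]:
    """Subtract the per-row mean; returns the centered observation and
    the removed translation (the weak-perspective model is translation
    invariant once landmarks are centered)."""
    W_raw = np.asarray(W_raw, dtype=float)
    t = W_raw.mean(axis=1)
    return Observation(W=W_raw - t[:, None], centered=True), t


def similarity_weights(
    obs: Observation,
    bases: ShapeBasisSet,
    gamma2: float | None = None,
    squared_distance: bool = True,
) -> SimilarityWeights:
    """Per-basis similarity penalty d_i = exp(dist(W, Pi B_i) / gamma2).

    dist is the squared Frobenius distance between the observation and
    the orthographic projection of basis i (plain distance when
    ``squared_distance`` is off).  A larger distance gives a larger d_i,
    so the quadratic term beta*||Z D||_F^2 penalises coefficients on
    bases that look unlike the observation.  ``gamma2=None`` uses the
    median distance over bases (self-scaling).
    """
    if obs.p != bases.p:
        raise ValueError("similarity_weights: point counts differ")
    dist = np.empty(bases.K)
    for i, B_i in enumerate(bases):
        diff = obs.W - PI @ B_i
        d2 = float(np.sum(diff * diff))
        dist[i] = d2 if squared_distance else np.sqrt(d2)
    if gamma2 is None:
        med = float(np.median(dist))
        gamma2 = med if med > 0 else 1.0
    if gamma2 <= 0:
        raise ValueError("similarity_weights: gamma2 must be positive")
    # Exponent capped to keep d finite on extreme inputs.
    d = np.exp(np.minimum(dist / gamma2, 500.0))
    return SimilarityWeights(d=d, gamma2=gamma2)


def update_M(Z: np.ndarray, Y: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    """M-step: blockwise spectral-norm prox of Z - Y/mu with weight alpha/mu."""
    if mu <= 0:
        raise ValueError("update_M: mu must be positive")
    P = Z - Y / mu
    K = P.shape[1] // 3
    M = np.empty_like(P)
    for i in range(K):
        M[:, 3 * i : 3 * i + 3] = prox_spectral_norm(P[:, 3 * i : 3 * i + 3], alpha / mu)
    return M


def update_Z(
    W: np.ndarray,
    B_tilde: np.ndarray,
    M_tilde: np.ndarray,
    Y: np.ndarray,
    mu: float,
    beta: float,
    D_diag: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Z-step: closed-form minimiser of the quadratic subproblem.

        Z = (W B~^T + mu M~ + Y) (B~ B~^T + mu I + beta D D^T)^{-1}

    Solved as a linear system (never an explicit inverse).  Returns the
    new Z and a condition-number estimate of the system matrix.
    """
    if mu <= 0:
        raise ValueError("update_Z: mu must be positive")
    n = B_tilde.shape[0]
    G = B_tilde @ B_tilde.T + mu * np.eye(n)
    if beta != 0.0:
        G[np.diag_indices(n)] += beta * D_diag**2
    rhs = W @ B_tilde.T + mu * M_tilde + Y
    # G is symmetric positive definite (mu > 0); solve G Z^T = rhs^T.
    Z = np.linalg.solve(G, rhs.T).T
    cond = float(np.linalg.cond(G))
    return Z, cond


def update_Y(Y: np.ndarray, M_tilde: np.ndarray, Z: np.ndarray, mu: float) -> np.ndarray:
    """Dual ascent: Y <- Y + mu (M~ - Z)."""
    if mu <= 0:
        raise ValueError("update_Y: mu must be positive")
    return Y + mu * (M_tilde - Z)


def update_mu(mu: float, delta1: float, delta2: float, ratio_threshold: float = 10.0) -> float:
    """Adaptive penalty: double mu when the constraint residual dominates,
    halve when the iterate-change residual dominates, else leave it."""
    if delta1 > ratio_threshold * delta2:
        return 2.0 * mu
    if delta2 > ratio_threshold * delta1:
        return mu / 2.0
    return mu


def residuals(
    M_tilde_new: np.ndarray, Z_new: np.ndarray, Z_old: np.ndarray
) -> tuple[float, float]:
    """Relative residuals: constraint gap delta1 = ||M~ - Z||/||Z_old||
    and iterate change delta2 = ||Z - Z_old||/||Z_old||."""
    denom = max(float(np.linalg.norm(Z_old)), 1e-12)
    d1 = float(np.linalg.norm(M_tilde_new - Z_new)) / denom
    d2 = float(np.linalg.norm(Z_new - Z_old)) / denom
    return d1, d2


def _lagrangian(W, B_tilde, M_tilde, Z, Y, mu, alpha, beta, D_diag):
    R = W - Z @ B_tilde
    K = M_tilde.shape[1] // 3
    spec = sum(
        float(np.linalg.norm(M_tilde[:, 3 * i : 3 * i + 3], 2)) for i in range(K)
    )
    gap = M_tilde - Z
    val = 0.5 * float(np.sum(R * R)) + alpha * spec
    val += float(np.sum(Y * gap)) + 0.5 * mu * float(np.sum(gap * gap))
    if beta != 0.0:
        ZD = Z * D_diag[None, :]
        val += 0.5 * beta * float(np.sum(ZD * ZD))
    return val


def admm_solve(
    obs: Observation,
    bases: ShapeBasisSet,
    config: SolverConfig,
    weights: SimilarityWeights | None = None,
) -> SolverState:
    """Run the ADMM iteration M-step -> Z-step -> dual ascent -> residual
    test -> penalty adaptation until both residuals drop below eps or the
    iteration cap is reached."""
    if not obs.centered:
        raise ValueError("admm_solve: observation must be centered")
    if bases.K < 1:
        raise ValueError("admm_solve: empty basis set")
    W = obs.W
    B_tilde = bases.B  # 3K x p
    beta = config.effective_beta
    if beta > 0 and weights is None:
        weights = similarity_weights(
            obs, bases, config.gamma2, config.squared_distance
        )
    D_diag = weights.diag if (beta > 0 and weights is not None) else np.ones(3 * bases.K)

    # Ridge least-squares initialisation of M = Z; Y = 0.
    n = B_tilde.shape[0]
    G0 = B_tilde @ B_tilde.T + 1e-6 * np.eye(n)
    Z = np.linalg.solve(G0, (W @ B_tilde.T).T).T
    state = SolverState(M_tilde=Z.copy(), Z=Z, Y=np.zeros_like(Z), mu=config.mu0)

    for t in range(config.max_iter):
        Z_old = state.Z
        M_new = update_M(state.Z, state.Y, state.mu, config.alpha)
        Z_new, cond = update_Z(W, B_tilde, M_new, state.Y, state.mu, beta, D_diag)
        if cond > 1e12:
            state.warnings.append(f"iteration {t}: ill-conditioned Z system (cond~{cond:.2e})")
        Y_new = update_Y(state.Y, M_new, Z_new, state.mu)
        if not (np.all(np.isfinite(M_new)) and np.all(np.isfinite(Z_new)) and np.all(np.isfinite(Y_new))):
            raise RuntimeError(f"admm_solve: non-finite iterate at iteration {t}")
        d1, d2 = residuals(M_new, Z_new, Z_old)
        state.M_tilde, state.Z, state.Y = M_new, Z_new, Y_new
        state.delta1, state.delta2 = d1, d2
        state.iteration = t + 1
        state.objective_trace.append(
            _lagrangian(W, B_tilde, M_new, Z_new, Y_new, state.mu, config.alpha, beta, D_diag)
        )
        if d1 < config.eps and d2 < config.eps:
            state.converged = True
            break
        state.mu = update_mu(state.mu, d1, d2, config.ratio_threshold)
    return state


def rotation_synchronize(
    M_list,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a shared rotation to the motion-factor blocks.

    Solves ``min_{c, R} sum_i ||M_i - c_i R||_F^2  s.t.  R R^T = I_2`` by
    alternating the closed-form coefficient update ``c_i = tr(M_i R^T)/2``
    (since ||R||_F^2 = 2) with the Procrustes rotation update
    ``R = procrustes(sum_i c_i M_i)``.  The global sign ambiguity
    ``(c, R) -> (-c, -R)`` is removed by forcing the first nonzero
    coefficient to be non-negative.
    """
    M_list = [np.asarray(M, dtype=float) for M in M_list]
    K = len(M_list)
    if K < 1:
        raise ValueError("rotation_synchronize: need at least one factor")
    norms = [np.linalg.norm(M) for M in M_list]
    if max(norms) <= 1e-300:
        raise ValueError("rotation_synchronize: all factors are zero (degenerate)")

    R = procrustes_2x3(M_list[int(np.argmax(norms))])
    prev_obj = np.inf
    c = np.zeros(K)
    for _ in range(max_iter):
        c = np.array([0.5 * float(np.sum(M * R)) for M in M_list])
        T = sum(ci * M for ci, M in zip(c, M_list))
        if np.linalg.norm(T) > 1e-300:
            R = procrustes_2x3(T)
        obj = sum(float(np.sum((M - ci * R) ** 2)) for ci, M in zip(c, M_list))
        if prev_obj - obj < tol:
            break
        prev_obj = obj
    c = np.array([0.5 * float(np.sum(M * R)) for M in M_list])
    nz = np.nonzero(np.abs(c) > 1e-12)[0]
    if nz.size and c[nz[0]] < 0:
        c, R = -c, -R
    return c, R


def assemble_shape(c: np.ndarray, R_bar: np.ndarray, bases: ShapeBasisSet) -> np.ndarray:
    """S = sum_i c_i * R * B_i with R the det(+1) lift of R_bar."""
    c = np.asarray(c, dtype=float)
    if c.size != bases.K:
        raise ValueError("assemble_shape: coefficient count must equal K")
    R = lift_rotation(R_bar)
    S = np.zeros((3, bases.p))
    for ci, B_i in zip(c, bases):
        S += ci * (R @ B_i)
    return S


def _split_blocks(M_tilde: np.ndarray) -> list[np.ndarray]:
    K = M_tilde.shape[1] // 3
    return [M_tilde[:, 3 * i : 3 * i + 3].copy() for i in range(K)]


def reconstruct(
    W_raw: np.ndarray, bases: ShapeBasisSet, config: SolverConfig | None = None
) -> ReconstructionResult:
    """Full per-frame pipeline: center -> similarity weights -> ADMM ->
    rotation synchronisation -> shape assembly."""
    config = config or SolverConfig()
    obs, t = center_observation(W_raw)
    if config.normalize_scale:
        scale = float(np.linalg.norm(obs.W))
        if scale > 0:
            obs = Observation(W=obs.W / scale, centered=True)
    state = admm_solve(obs, bases, config)
    c, R_bar = rotation_synchronize(_split_blocks(state.M_tilde))
    S = assemble_shape(c, R_bar, bases)
    return ReconstructionResult(
        S=S,
        motion=MotionEstimate(c=c, R_bar=R_bar, M_list=_split_blocks(state.M_tilde)),
        state=state,
        translation=t,
    )


def reconstruct_sequence(
    W_frames, bases: ShapeBasisSet, config: SolverConfig | None = None
) -> list[ReconstructionResult]:
    """Reconstruct each frame independently (the model is per-frame)."""
    return [reconstruct(W, bases, config) for W in W_frames]
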