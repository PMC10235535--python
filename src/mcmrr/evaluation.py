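"""Reconstruction-error metrics and ablation comparisons.

The headline metric is the mean per-frame squared Frobenius error

    xi = (1/F) * sum_t || S~_t - S_t ||_F^2

between reconstructed and true 3D shapes.  Because weak-perspective
reconstruction is determined only up to a rigid motion and a depth
(z-axis) flip, the default aligns each estimated frame onto the truth by
orthogonal Procrustes (rotation + translation, with a reflection trial)
before measuring; unaligned error is available for gauge-fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import SolverConfig, reconstruct_sequence
from .synthetic import GroundTruth

__all__ = ["SequenceError", "align_shape", "mean_error", "error_decrease_percent", "ablation_table"]

_ZFLIP = np.diag([1.0, 1.0, -1.0])


@dataclass(frozen=True)
class SequenceError:
    """Per-sequence error summary (mean, per-frame values, SD)."""

    xi: float
    per_frame_errors: np.ndarray
    aligned: bool

    @property
    def mean_sd(self) -> tuple[float, float]:
        return self.xi, float(np.std(self.per_frame_errors))


def align_shape(S_est: np.ndarray, S_true: np.ndarray) -> np.ndarray:
    """Optimal rigid alignment of one 3 x p shape onto another.

    Centers both, fits the best proper rotation (Kabsch), and also tries
    the depth-flipped estimate, returning whichever aligned shape is
    closer to the truth.  Translation of the truth is restored.
    """
    mu_e = S_est.mean(axis=1, keepdims=True)
    mu_t = S_true.mean(axis=1, keepdims=True)
    A = S_est - mu_e
    Bc = S_true - mu_t
    best = None
    for cand in (A, _ZFLIP @ A):
        H = Bc @ cand.T
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(U @ Vt))
        R = U @ np.diag([1.0, 1.0, d]) @ Vt
        aligned = R @ cand + mu_t
        err = float(np.sum((aligned - S_true) ** 2))
        if best is None or err < best[0]:
            best = (err, aligned)
    return best[1]


def mean_error(S_est, S_true, align: bool = True) -> SequenceError:
    """Mean squared Frobenius error over frames, optionally after
    per-frame rigid (+ z-flip) alignment."""
    S_est = [np.asarray(S, dtype=float) for S in S_est]
    S_true = [np.asarray(S, dtype=float) for S in S_true]
    if len(S_est) != len(S_true):
        raise ValueError("mean_error: sequence lengths differ")
    errs = np.empty(len(S_est))
    for t, (Se, St) in enumerate(zip(S_est, S_true)):
        if Se.shape != St.shape:
            raise ValueError(f"mean_error: frame {t} shape mismatch")
        if align:
            Se = align_shape(Se, St)
        errs[t] = float(np.sum((Se - St) ** 2))
    return SequenceError(xi=float(errs.mean()), per_frame_errors=errs, aligned=align)


def error_decrease_percent(xi_ref: float, xi_new: float) -> float:
    """Percentage decrease of xi_new relative to the reference xi_ref:
    100 * (xi_ref - xi_new) / xi_ref."""
    if xi_ref <= 0:
        raise ValueError("error_decrease_percent: reference error must be positive")
    return 100.0 * (xi_ref - xi_new) / xi_ref


def ablation_table(
    gt: GroundTruth,
    variants=("cra", "cra-en", "cra-sc", "mcmrr"),
    config: SolverConfig | None = None,
    bases=None,
) -> list[dict]:
    """Run each solver variant over a ground-truth sequence and report
    the mean and SD of the aligned per-frame errors.

    ``bases`` defaults to the true generative bases; pass a learned
    basis set to include dictionary-learning error in the comparison.
    """
    base_cfg = config or SolverConfig()
    allowed = {"cra", "cra-en", "cra-sc", "mcmrr"}
    bad = set(variants) - allowed
    if bad:
        raise ValueError(f"ablation_table: unknown variants {sorted(bad)}")
    bases = bases if bases is not None else gt.basis_set
    rows = []
    for variant in variants:
        cfg = SolverConfig(
            alpha=base_cfg.alpha,
            beta=base_cfg.beta,
            gamma2=base_cfg.gamma2,
            eps=base_cfg.eps,
            max_iter=base_cfg.max_iter,
            mu0=base_cfg.mu0,
            ratio_threshold=base_cfg.ratio_threshold,
            variant=variant,
            squared_distance=base_cfg.squared_distance,
            normalize_scale=base_cfg.normalize_scale,
        )
        results = reconstruct_sequence(gt.observations, bases, cfg)
        err = mean_error([r.S for r in results], gt.shapes_true, align=True)
        mu, sd = err.mean_sd
        rows.append({"variant": variant, "mean": mu, "sd": sd})
    return rows
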