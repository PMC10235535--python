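"""Mocap-like synthetic sequences with known ground truth.

Emulates articulated-skeleton motion-capture data: 3D shapes are sparse
non-negative combinations of K_true ground-truth bases, rotated per
frame, and orthographically projected to 2D with optional Gaussian
landmark noise — exactly the generative weak-perspective shape-space
model the solver inverts.  Every stage of the pipeline is therefore
testable without external mocap downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation, Slerp

from .basis import ShapeBasisSet

__all__ = ["SyntheticSpec", "GroundTruth", "make_skeleton_bases", "generate", "export_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator.

    coeff_sparsity is the expected number of active bases per frame;
    noise_sigma is the landmark-noise SD in the same (dimensionless)
    coordinate units as the unit-Frobenius-norm bases.
    """

    p: int = 12
    K_true: int = 3
    F_train: int = 60
    F_test: int = 10
    coeff_sparsity: float = 2.0
    noise_sigma: float = 0.0
    rotation_mode: str = "random"
    seed: int = 0

    def __post_init__(self):
        if self.p < 4:
            raise ValueError("SyntheticSpec: p >= 4 required")
        if self.K_true < 1:
            raise ValueError("SyntheticSpec: K_true >= 1 required")
        if self.noise_sigma < 0:
            raise ValueError("SyntheticSpec: noise_sigma >= 0 required")
        if self.rotation_mode not in ("identity", "random", "smooth"):
            raise ValueError("SyntheticSpec: unknown rotation_mode")


@dataclass
class GroundTruth:
    """Generated sequence with all latent variables exposed."""

    spec: SyntheticSpec
    bases_true: list[np.ndarray]
    train_shapes: list[np.ndarray]
    coeffs_true: np.ndarray          # F_test x K_true, non-negative
    rotations_true: list[np.ndarray]  # F_test 3x3 rotations
    shapes_true: list[np.ndarray]     # F_test 3 x p (rotated)
    observations: list[np.ndarray]    # F_test 2 x p (noisy)

    @property
    def basis_set(self) -> ShapeBasisSet:
        B = np.vstack(self.bases_true)
        return ShapeBasisSet(B=B, K=len(self.bases_true), p=self.bases_true[0].shape[1])


def _stick_figure(p: int) -> np.ndarray:
    """Fixed stick-figure template: a 3D chain of p joints (a bent
    'spine' with limbs fanning out), centered, unit Frobenius norm."""
    t = np.linspace(0.0, 1.0, p)
    pts = np.stack(
        [
            np.sin(2.1 * np.pi * t),
            2.0 * t - 1.0,
            0.4 * np.cos(3.3 * np.pi * t),
        ]
    )
    pts = pts - pts.mean(axis=1, keepdims=True)
    return pts / np.linalg.norm(pts)


def make_skeleton_bases(p: int, K_true: int, seed: int = 0) -> list[np.ndarray]:
    """K_true centered, unit-norm 3 x p bases: a stick-figure template
    plus smooth seeded deformations of it, pairwise well separated."""
    if p < 4:
        raise ValueError("make_skeleton_bases: p >= 4 required")
    rng = np.random.default_rng(seed)
    template = _stick_figure(p)
    bases = [template]
    attempts = 0
    while len(bases) < K_true:
        attempts += 1
        # Smooth deformation: Gaussian-filtered white noise along the
        # joint chain.  A narrow kernel keeps full spectral support, so
        # the stacked 3K x p basis matrix stays well conditioned (the
        # motion factors are identifiable when p >= 3K + 1; per-axis
        # centering removes one dimension).
        deform = gaussian_filter1d(
            rng.normal(0.0, 0.35, (3, p)), sigma=0.8, axis=1, mode="nearest"
        )
        cand = template + deform
        cand = cand - cand.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(cand)
        if nrm < 1e-12:
            continue
        cand /= nrm
        if all(np.linalg.norm(cand - b) > 0.1 for b in bases) or attempts > 200:
            bases.append(cand)
    return bases


def _draw_coeffs(rng, F: int, K: int, sparsity: float) -> np.ndarray:
    """Non-negative sparse coefficients: |N(0,1)| masked Bernoulli to the
    target expected support size; all-zero rows are redrawn."""
    prob = min(1.0, sparsity / K)
    C = np.empty((F, K))
    for f in range(F):
        while True:
            mask = rng.random(K) < prob
            if mask.any():
                break
        C[f] = np.abs(rng.normal(0.0, 1.0, K)) * mask
        if C[f].sum() == 0:
            C[f, int(rng.integers(K))] = abs(rng.normal(0.0, 1.0))
    return C


def _random_rotation(rng) -> Rotation:
    # Uniform over SO(3): normalised Gaussian quaternion.
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))


def _draw_rotations(rng, F: int, mode: str) -> list[np.ndarray]:
    if mode == "identity":
        return [np.eye(3) for _ in range(F)]
    if mode == "random":
        return [_random_rotation(rng).as_matrix() for _ in range(F)]
    # smooth: spherical interpolation between two random end rotations,
    # emulating a slowly moving mocap camera.
    ends = Rotation.concatenate([_random_rotation(rng), _random_rotation(rng)])
    if F == 1:
        return [ends[0].as_matrix()]
    slerp = Slerp([0.0, 1.0], ends)
    times = np.linspace(0.0, 1.0, F)
    return [r.as_matrix() for r in slerp(times)]


def generate(spec: SyntheticSpec) -> GroundTruth:
    """Draw a full ground-truth bundle from the generative model.

    Training shapes are un-rotated basis combinations (the dictionary
    learner consumes canonical-pose 3D data); test frames additionally
    carry per-frame rotations and are projected orthographically, with
    noise added to the 2D observations only.
    """
    rng = np.random.default_rng(spec.seed)
    bases = make_skeleton_bases(spec.p, spec.K_true, seed=spec.seed)

    C_train = _draw_coeffs(rng, spec.F_train, spec.K_true, spec.coeff_sparsity)
    train_shapes = [
        sum(C_train[f, i] * bases[i] for i in range(spec.K_true))
        for f in range(spec.F_train)
    ]

    C_test = _draw_coeffs(rng, spec.F_test, spec.K_true, spec.coeff_sparsity)
    rotations = _draw_rotations(rng, spec.F_test, spec.rotation_mode)
    shapes, obs = [], []
    for f in range(spec.F_test):
        S0 = sum(C_test[f, i] * bases[i] for i in range(spec.K_true))
        S = rotations[f] @ S0
        W = S[:2, :].copy()
        if spec.noise_sigma > 0:
            W += rng.normal(0.0, spec.noise_sigma, W.shape)
        shapes.append(S)
        obs.append(W)
    return GroundTruth(
        spec=spec,
        bases_true=bases,
        train_shapes=train_shapes,
        coeffs_true=C_test,
        rotations_true=rotations,
        shapes_true=shapes,
        observations=obs,
    )


def export_fixture(gt: GroundTruth, out_dir) -> dict[str, Path]:
    """Write training CSV (3D), observation CSV (2D) and a truth NPZ.

    The CSVs use the io module's landmark table layout and round-trip
    losslessly through it (within float-format tolerance).
    """
    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "train": out / "train_3d.csv",
        "obs": out / "observations_2d.csv",
        "truth": out / "truth.npz",
    }
    mio.write_landmarks_csv(paths["train"], gt.train_shapes, dims=3)
    mio.write_landmarks_csv(paths["obs"], gt.observations, dims=2)
    np.savez(
        paths["truth"],
        bases=np.stack(gt.bases_true),
        coeffs=gt.coeffs_true,
        rotations=np.stack(gt.rotations_true),
        shapes=np.stack(gt.shapes_true),
        observations=np.stack(gt.observations),
    )
    return paths
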