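"""Readers and writers for landmark tables, bases and run configuration.

Formats
-------
Landmark CSV: header ``frame,point,x,y[,z]``; 0-based integer frame and
point indices; every frame must carry the same point set.  NPZ bundles
are the binary interchange (array ``landmarks`` of shape F x dims x p).
Learned bases are written as NPZ (``B``, ``K``, ``p``) with a JSON
metadata sidecar recording the hyperparameters.  Configuration is
YAML/JSON with unknown keys rejected.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import ShapeBasisSet

__all__ = [
    "RunConfig",
    "read_landmarks",
    "write_landmarks_csv",
    "write_landmarks_npz",
    "write_bases",
    "read_bases",
    "load_config",
    "dump_config",
]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class RunConfig:
    """All pipeline hyperparameters with validated defaults."""

    # dictionary learning
    K: int = 3
    lambda_: float = 0.01
    tau: float = 0.5
    phi1: float = 1e-2
    phi2: float = 1e-2
    learn_max_iter: int = 5000
    learn_tol: float = 1e-6
    # ADMM solver
    alpha: float = 0.01
    beta: float = 0.001
    gamma2: float | None = None
    eps: float = 1e-4
    mu0: float = 1.0
    ratio_threshold: float = 10.0
    solver_max_iter: int = 1000
    variant: str = "mcmrr"
    squared_distance: bool = True
    normalize_scale: bool = False
    # misc
    seed: int = 0

    def __post_init__(self):
        checks = [
            ("K", self.K >= 1),
            ("lambda_", self.lambda_ >= 0),
            ("tau", 0.0 <= self.tau <= 1.0),
            ("phi1", self.phi1 > 0),
            ("phi2", self.phi2 > 0),
            ("learn_max_iter", self.learn_max_iter >= 1),
            ("learn_tol", self.learn_tol > 0),
            ("alpha", self.alpha >= 0),
            ("beta", self.beta >= 0),
            ("gamma2", self.gamma2 is None or self.gamma2 > 0),
            ("eps", self.eps > 0),
            ("mu0", self.mu0 > 0),
            ("ratio_threshold", self.ratio_threshold > 0),
            ("solver_max_iter", self.solver_max_iter >= 1),
            ("variant", self.variant in ("mcmrr", "cra", "cra-en", "cra-sc")),
        ]
        for key, ok in checks:
            if not ok:
                raise ValueError(f"RunConfig: invalid value for '{key}'")


def _frames_from_table(df: pd.DataFrame, dims: int) -> list[np.ndarray]:
    cols = ["x", "y", "z"][:dims]
    frames = []
    expected_points = None
    for f, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("point")
        pts = grp["point"].to_numpy()
        if expected_points is None:
            expected_points = pts
        elif not np.array_equal(pts, expected_points):
            raise FormatError(f"frame {f}: point set differs from first frame (ragged table)")
        frames.append(grp[cols].to_numpy().T.astype(float))
    return frames


def read_landmarks(path, dims: int) -> list[np.ndarray]:
    """Load a landmark sequence as a list of dims x p arrays.

    Accepts the CSV table format or an NPZ with a ``landmarks`` array.
    """
    if dims not in (2, 3):
        raise ValueError("read_landmarks: dims must be 2 or 3")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"read_landmarks: no such file: {path}")
    if path.suffix == ".npz":
        with np.load(path) as z:
            if "landmarks" not in z:
                raise FormatError(f"{path}: NPZ bundle lacks a 'landmarks' array")
            arr = z["landmarks"]
        if arr.ndim != 3 or arr.shape[1] != dims:
            raise FormatError(f"{path}: expected landmarks of shape (F, {dims}, p), got {arr.shape}")
        return [arr[f].astype(float) for f in range(arr.shape[0])]

    df = pd.read_csv(path)
    need = ["frame", "point", "x", "y"] + (["z"] if dims == 3 else [])
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if dims == 2 and "z" in df.columns:
        raise FormatError(f"{path}: file has a z column but 2D data was requested")
    dup = df.duplicated(subset=["frame", "point"])
    if dup.any():
        row = int(dup.idxmax())
        raise FormatError(f"{path}: duplicate (frame, point) pair at row {row}")
    if not np.all(np.isfinite(df[need[2:]].to_numpy())):
        raise FormatError(f"{path}: non-finite coordinate values")
    return _frames_from_table(df, dims)


def write_landmarks_csv(path, frames, dims: int) -> None:
    """Write a landmark sequence in the CSV table format."""
    cols = ["x", "y", "z"][:dims]
    records = []
    for f, arr in enumerate(frames):
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] != dims:
            raise ValueError(f"write_landmarks_csv: frame {f} has {arr.shape[0]} rows, expected {dims}")
        for j in range(arr.shape[1]):
            records.append([f, j, *arr[:, j]])
    df = pd.DataFrame(records, columns=["frame", "point", *cols])
    df.to_csv(path, index=False, float_format="%.12g")


def write_landmarks_npz(path, frames) -> None:
    np.savez(path, landmarks=np.stack([np.asarray(f, dtype=float) for f in frames]))


def write_bases(path, bases: ShapeBasisSet, hyperparams: dict | None = None) -> None:
    """Write bases as NPZ plus a JSON sidecar with the hyperparameters."""
    path = Path(path)
    np.savez(path, B=bases.B, K=bases.K, p=bases.p)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"K": bases.K, "p": bases.p, "hyperparameters": hyperparams or {}}, indent=2)
    )


def read_bases(path) -> ShapeBasisSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"read_bases: no such file: {path}")
    with np.load(path) as z:
        return ShapeBasisSet(B=z["B"], K=int(z["K"]), p=int(z["p"]))


def load_config(path=None) -> RunConfig:
    """Load YAML/JSON config; absent keys take defaults, unknown keys
    are rejected with the offending name."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    # allow 'lambda' as a YAML-friendly alias for lambda_
    if "lambda" in data:
        data["lambda_"] = data.pop("lambda")
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def dump_config(cfg: RunConfig) -> str:
    """Stable YAML rendering of a fully-resolved config."""
    return yaml.safe_dump(asdict(cfg), sort_keys=True)
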