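# mcmrr — multi-constraint 3D shape reconstruction from 2D landmarks

`mcmrr` reconstructs time-varying 3D shape from 2D landmark tracks — the
non-rigid structure-from-motion (NRSFM) problem, here in the single-frame
regime: given a dictionary of 3D shape bases learned from motion-capture-like
training data, each 2D frame is inverted independently into a 3D pose.  It is
aimed at researchers working with articulated-skeleton landmark data (human
motion capture, pose estimation) who need a reproducible, testable baseline
for shape-space reconstruction.

## Model

A non-rigid shape is a linear combination of K bases `B_i ∈ ℝ^{3×p}`:

    S = Σ_i c_i R_i B_i ,

and under weak-perspective projection the 2D observation `W ∈ ℝ^{2×p}` is

    W = Σ_i M_i B_i ,    M_i = c_i R̃_i ∈ ℝ^{2×3} ,

with `R̃_i` the first two rows of a rotation.  The package implements:

1. **Basis learning** — an elastic-net dictionary model on the stacked
   training set `A ∈ ℝ^{3p×F}`:

       min_{N,X} ½‖A − NX‖_F² + λ(τ‖X‖₁ + (1−τ)‖X‖₂²)
       s.t. ‖N_i‖_F ≤ 1 ,  X_ij ≥ 0 ,

   solved by alternating projected gradient descent with backtracking.

2. **Shape/motion estimation** — a penalised least-square model with a
   spectral-norm relaxation of the orthogonality constraint and a
   similarity penalty between the observation and each basis's projection:

       min_{M̃,Z} ½‖W − ZB̃‖_F² + α Σ_i ‖M_i‖₂ + β/2 ‖ZD‖_F²   s.t. M̃ = Z ,

   with `D = diag(d) ⊗ I₃`, `d_i = exp(‖W − ΠB_i‖_F²/γ²)`, solved by ADMM
   (blockwise spectral-norm prox for M̃, closed-form linear solve for Z,
   dual ascent, adaptive penalty μ).

3. **Refinement** — rotation synchronisation `min_{c,R̄} Σ_i ‖M_i − c_i R̄‖_F²`
   with `R̄R̄ᵀ = I₂`, solved by alternating closed-form steps, then
   `S = Σ_i c_i R B_i` with `R` the proper-rotation lift of `R̄`.

A synthetic generator produces mocap-like sequences with full ground truth,
so the whole pipeline is testable without external data.

## Worked example

```sh
python examples/03_reconstruct_from_2d.py
```

prints (exact numbers depend on the build's BLAS only through the last digits):

```
ADMM converged: True in 31 iterations (residuals 7.68e-05, 8.04e-05)
estimated coefficients: [0.288 0.004 0.009]
true coefficients:      [0.358 0.    0.   ]
aligned squared-Frobenius error: 3.5896e-03
```

The solver identifies the single active basis (first coefficient dominant,
distractor coefficients near zero) and the reconstructed 3D shape differs
from the ground truth by an aligned squared error of ~4e-3 — small relative
to the unit-norm shape scale.  Alignment (rotation + translation + depth
flip) is applied before measuring because a 2D projection determines 3D
shape only up to those transforms.

The other examples cover simulation (`01`), dictionary learning (`02`) and
the ablation comparison between solver variants (`04`).

## Command line

```sh
mcmrr simulate     --spec spec.yaml --out data/
mcmrr learn-bases  --train data/train_3d.csv --config cfg.yaml --out bases.npz
mcmrr reconstruct  --bases bases.npz --obs data/observations_2d.csv --out est.npz
mcmrr evaluate     --est est.npz --truth data/truth.npz
mcmrr ablate       --spec spec.yaml --out table.csv
```

Landmark files are CSV (`frame,point,x,y[,z]`, 0-based indices) or NPZ
bundles; configuration is YAML/JSON with validated keys.

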