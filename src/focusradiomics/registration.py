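"""Slice-wise 2D affine co-registration of a dynamic series.

The four contrast-enhanced volumes are registered slice-by-slice to the
corresponding slice of the unenhanced volume (T0) by minimising the mean
square difference of intensities.  The optimiser is a coarse-to-fine
Gauss-Newton iteration on the 6 affine parameters: at each step the
floating image and its spatial gradients are warped under the current
transform, the normal equations of the linearised residual are solved, and
the step is damped whenever it fails to decrease the objective, so the
accepted objective is non-increasing.

Because enhanced and unenhanced images differ systematically in brightness,
both slices are standardised to zero mean / unit variance before the MSE is
evaluated, decoupling enhancement-driven intensity change from geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .affine import Affine2D, resample_slice
from .synthetic import DynamicSeries


@dataclass
class RegistrationConfig:
    pyramid_levels: int = 3
    max_iterations: int = 50             # Gauss-Newton iterations per level
    convergence_tolerance: float = 1e-7  # relative MSE change
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be > 0")
        if self.interpolation != "bilinear":
            raise ValueError("only bilinear interpolation is supported")


def _standardise(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    return (img - img.mean()) / img.std()


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    return ndimage.gaussian_filter(img, factor / 2.0)[::factor, ::factor]


def _core(shape: tuple) -> tuple:
    """Central region used for the metric, excluding resampling borders."""
    m = [max(2, int(round(0.12 * s))) for s in shape]
    return tuple(slice(mi, s - mi) for mi, s in zip(m, shape))


def _params_to_affine(p: np.ndarray) -> Affine2D:
    m = np.eye(2) + np.array([[p[0], p[1]], [p[2], p[3]]])
    return Affine2D(m, np.array([p[4], p[5]]))


def _warp(img: np.ndarray, p: np.ndarray) -> np.ndarray:
    m = np.eye(2) + np.array([[p[0], p[1]], [p[2], p[3]]])
    return ndimage.affine_transform(img, m, offset=(p[4], p[5]), order=1,
                                    mode="nearest")


def _mse(target: np.ndarray, floating: np.ndarray, p: np.ndarray,
         core: tuple) -> float:
    if abs(np.linalg.det(np.eye(2)
                         + np.array([[p[0], p[1]], [p[2], p[3]]]))) <= 1e-8:
        return np.inf
    d = target[core] - _warp(floating, p)[core]
    return float(np.mean(d * d))


def _gauss_newton(target: np.ndarray, floating: np.ndarray, p0: np.ndarray,
                  max_iter: int, tol: float) -> np.ndarray:
    """Damped Gauss-Newton on MSE(target, warp(floating, p))."""
    core = _core(target.shape)
    gr, gc = np.gradient(floating)
    rows, cols = np.mgrid[0:target.shape[0], 0:target.shape[1]].astype(float)
    rows_c, cols_c = rows[core], cols[core]
    p = p0.copy()
    cost = _mse(target, floating, p, core)
    for _ in range(max_iter):
        warped = _warp(floating, p)[core]
        jr = _warp(gr, p)[core].ravel()
        jc = _warp(gc, p)[core].ravel()
        r = (target[core] - warped).ravel()
        # d(warp)/dp: rows of the Jacobian of the warped intensity
        A = np.column_stack([jr * rows_c.ravel(), jr * cols_c.ravel(),
                             jc * rows_c.ravel(), jc * cols_c.ravel(),
                             jr, jc])
        ata = A.T @ A
        ata[np.diag_indices_from(ata)] *= 1.0 + 1e-8
        try:
            step = np.linalg.solve(ata, A.T @ r)
        except np.linalg.LinAlgError:
            break
        improved = False
        for scale in (1.0, 0.5, 0.25, 0.125):
            cand = p + scale * step
            c = _mse(target, floating, cand, core)
            if c < cost:
                rel = (cost - c) / cost if cost > 0 else 0.0
                p, cost, improved = cand, c, True
                if rel < tol:
                    return p
                break
        if not improved:
            break
    return p


def register_slice(target: np.ndarray, floating: np.ndarray,
                   cfg: RegistrationConfig | None = None) -> Affine2D:
    """Affine minimising MSE(target, resample(floating, A)).

    Returns the pull-back transform that resamples `floating` onto `target`.
    Constant target or floating images yield the identity with the
    ``degenerate`` flag set.  The achieved MSE never exceeds the MSE at the
    identity: if optimisation fails to improve on it, the identity is
    returned.
    """
    cfg = cfg or RegistrationConfig()
    target = np.asarray(target, dtype=float)
    floating = np.asarray(floating, dtype=float)
    if target.shape != floating.shape:
        raise ValueError("target and floating must have equal shapes")
    if target.std() == 0 or floating.std() == 0:
        warnings.warn("constant image: registration skipped, identity returned")
        return Affine2D(np.eye(2), np.zeros(2), degenerate=True)

    tgt = _standardise(target)
    flo = _standardise(floating)

    # pyramid factors, coarsest first; drop levels that would leave < 12 px
    factors = [2 ** (cfg.pyramid_levels - 1 - i)
               for i in range(cfg.pyramid_levels)]
    factors = [f for f in factors if min(target.shape) // f >= 12] or [1]

    p = np.zeros(6)
    for f in factors:
        tgt_l, flo_l = _downsample(tgt, f), _downsample(flo, f)
        p[4:] /= f
        p = _gauss_newton(tgt_l, flo_l, p, cfg.max_iterations,
                          cfg.convergence_tolerance)
        p[4:] *= f

    core = _core(tgt.shape)
    final = _mse(tgt, flo, p, core)
    at_identity = _mse(tgt, flo, np.zeros(6), core)
    if not np.isfinite(final) or final > at_identity:
        return Affine2D.identity()
    return _params_to_affine(p)


def register_series(series: DynamicSeries,
                    cfg: RegistrationConfig | None = None):
    """Register every slice of T1-T4 to the corresponding T0 slice.

    Returns the resampled series (same shape and spacing) plus the recovered
    transforms as ``transforms[t-1][z]``.  The lesion mask is never
    resampled: segmentation is defined on the registered series.
    """
    cfg = cfg or RegistrationConfig()
    data = series.data.copy()
    n_slices = data.shape[1]
    transforms = []
    for ti in range(1, 5):
        per_slice = []
        for z in range(n_slices):
            aff = register_slice(data[0, z], series.data[ti, z], cfg)
            if not aff.is_identity(atol=0):
                data[ti, z] = resample_slice(series.data[ti, z], aff)
            per_slice.append(aff)
        transforms.append(per_slice)
    return DynamicSeries(data, series.spacing, series.times), transforms
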