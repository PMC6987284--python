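"""2D affine transforms in the pull-back (resampling) convention.

An :class:`Affine2D` maps *output* pixel coordinates (row, col) to the
*input* coordinates that are sampled: ``x_in = matrix @ x_out + translation``.
This is exactly the convention of :func:`scipy.ndimage.affine_transform`,
so a transform can be handed to the resampler unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class Affine2D:
    """Pull-back 2D affine: output pixel ``x`` samples input at ``M x + t``."""

    matrix: np.ndarray
    translation: np.ndarray
    degenerate: bool = False  # set when estimated from constant images

    def __post_init__(self) -> None:
        m = np.array(self.matrix, dtype=float).reshape(2, 2)
        t = np.array(self.translation, dtype=float).reshape(2)
        if abs(float(np.linalg.det(m))) <= 1e-8:
            raise ValueError("affine matrix is numerically singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls(np.eye(2), np.zeros(2))

    def inverse(self) -> "Affine2D":
        minv = np.linalg.inv(self.matrix)
        return Affine2D(minv, -minv @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (…, 2) output coordinates to input coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.matrix, np.eye(2), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Affine2D":
        return cls(np.asarray(d["matrix"]), np.asarray(d["translation"]),
                   bool(d.get("degenerate", False)))


def compose(first: Affine2D, second: Affine2D) -> Affine2D:
    """Transform equivalent to resampling with `first`, then with `second`."""
    m = first.matrix @ second.matrix
    t = first.matrix @ second.translation + first.translation
    return Affine2D(m, t)


def resample_slice(image: np.ndarray, transform: Affine2D, order: int = 1,
                   mode: str = "nearest") -> np.ndarray:
    """Resample a 2D image under a pull-back affine (bilinear by default)."""
    return ndimage.affine_transform(
        np.asarray(image, dtype=float), transform.matrix,
        offset=transform.translation, order=order, mode=mode)


def center_displacement(a: Affine2D, b: Affine2D, shape: tuple) -> float:
    """Euclidean distance, in pixels, between where two transforms send the
    slice centre — a scalar 'translation error' that stays meaningful when
    small rotations/shears are present."""
    c = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    return float(np.linalg.norm(a.apply(c) - b.apply(c)))
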