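"""In-plane similarity transforms: the currency of both alignment stages.

An :class:`Affine2D` is the decomposed transform ``T(tx, ty) . R(theta) . S(s)``
acting about the image centre.  Points are ``(x, y)`` with ``x`` along columns
and ``y`` along rows; ``theta`` is in degrees, positive counter-clockwise in
``(x, y)`` axes (clockwise on screen, where y points down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class Affine2D:
    """Decomposed in-plane similarity transform.

    Parameters
    ----------
    tx, ty : float
        Translation in pixels (x = columns, y = rows).
    theta : float
        Rotation in degrees about the image centre.
    s : float
        Isotropic scale, strictly positive.
    """

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.s > 0):
            raise ValueError(f"scale must be positive, got {self.s}")

    # ------------------------------------------------------------------ algebra
    @property
    def linear(self) -> np.ndarray:
        """2x2 linear part ``s . R(theta)`` in (x, y) coordinates."""
        th = math.radians(self.theta)
        c, s_ = math.cos(th), math.sin(th)
        return self.s * np.array([[c, -s_], [s_, c]])

    def compose(self, other: "Affine2D") -> "Affine2D":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        la = self.linear
        t = np.array([self.tx, self.ty]) + la @ np.array([other.tx, other.ty])
        return Affine2D(
            tx=float(t[0]),
            ty=float(t[1]),
            theta=self.theta + other.theta,
            s=self.s * other.s,
        )

    def inverse(self) -> "Affine2D":
        li = np.linalg.inv(self.linear)
        t = -li @ np.array([self.tx, self.ty])
        return Affine2D(
            tx=float(t[0]), ty=float(t[1]), theta=-self.theta, s=1.0 / self.s
        )

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.tx, self.ty, self.theta, self.s)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            abs(self.tx) < tol
            and abs(self.ty) < tol
            and abs(self.theta) < tol
            and abs(self.s - 1) < tol
        )

    # ------------------------------------------------------------- application
    def apply_points(self, pts: np.ndarray, center: tuple[float, float]) -> np.ndarray:
        """Map ``(n, 2)`` points (x, y) through the transform about ``center``."""
        pts = np.asarray(pts, dtype=float)
        c = np.asarray(center, dtype=float)
        t = np.array([self.tx, self.ty])
        return (self.linear @ (pts - c).T).T + c + t

    def warp(
        self,
        image: np.ndarray,
        order: int = 1,
        cval: float = 0.0,
    ) -> np.ndarray:
        """Resample ``image`` so that ``out(p) = in(A^-1 p)`` about the centre.

        ``order=1`` (bilinear) for intensities, ``order=0`` (nearest) for
        label masks.  Multi-channel images are warped per channel.
        """
        if image.ndim == 3:
            cvals = np.broadcast_to(np.asarray(cval, dtype=float), (image.shape[-1],))
            return np.stack(
                [
                    self.warp(image[..., k], order=order, cval=float(cvals[k]))
                    for k in range(image.shape[-1])
                ],
                axis=-1,
            )
        h, w = image.shape
        # centre in (x, y)
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        inv = self.inverse()
        lin_xy = inv.linear
        # scipy works in (row, col) = (y, x): conjugate the linear part by the swap
        lin_rc = np.array([[lin_xy[1, 1], lin_xy[1, 0]], [lin_xy[0, 1], lin_xy[0, 0]]])
        t_xy = np.array([inv.tx, inv.ty])
        # in_coord = L (out - c) + c + t  (all in rc order)
        c_rc = np.array([cy, cx])
        off = c_rc + t_xy[::-1] - lin_rc @ c_rc
        return ndimage.affine_transform(
            np.asarray(image, dtype=float),
            lin_rc,
            offset=off,
            order=order,
            mode="constant",
            cval=cval,
            prefilter=(order > 1),
        )

    # -------------------------------------------------------------------- i/o
    def to_list(self) -> list[float]:
        """Serialize as ``[tx, ty, theta_deg, scale]``."""
        return [self.tx, self.ty, self.theta, self.s]

    @classmethod
    def from_list(cls, v) -> "Affine2D":
        return cls(tx=float(v[0]), ty=float(v[1]), theta=float(v[2]), s=float(v[3]))

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls()


def warp_mask(mask: np.ndarray, transform: Affine2D, cval: int = 0) -> np.ndarray:
    """Nearest-neighbour warp of an integer label mask."""
    out = transform.warp(mask.astype(float), order=0, cval=float(cval))
    return out.astype(mask.dtype)
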