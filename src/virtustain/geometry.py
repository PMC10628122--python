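"""Homography utilities shared by the synthetic renderer and the registration stage.

A homography is represented as a plain 3x3 ``float64`` array acting on
homogeneous ``(x, y, 1)`` column vectors, normalized so that ``H[2, 2] == 1``.
Throughout the package the convention is that a homography maps
fluorescence-frame coordinates to brightfield-frame coordinates.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "identity_homography",
    "make_homography",
    "normalize_homography",
    "apply_homography",
    "is_identity",
    "corner_error",
]


def identity_homography() -> np.ndarray:
    return np.eye(3, dtype=float)


def normalize_homography(H: np.ndarray) -> np.ndarray:
    """Return a copy of ``H`` scaled so the bottom-right entry is 1."""
    H = np.asarray(H, dtype=float)
    if H.shape != (3, 3):
        raise ValueError(f"homography must be 3x3, got {H.shape}")
    if abs(H[2, 2]) < 1e-12:
        raise ValueError("homography has H[2,2] == 0; cannot normalize")
    if abs(np.linalg.det(H)) < 1e-12:
        raise ValueError("homography is singular")
    return H / H[2, 2]


def make_homography(
    tx: float = 0.0,
    ty: float = 0.0,
    theta_deg: float = 0.0,
    scale: float = 1.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Similarity transform (rotation ``theta_deg`` about ``center``, isotropic
    ``scale``, then translation ``(tx, ty)``) as a 3x3 homography.

    ``center`` defaults to the origin; pass the frame center to keep rotated
    content in view.
    """
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[scale * c, -scale * s, 0.0], [scale * s, scale * c, 0.0], [0.0, 0.0, 1.0]])
    if center is not None:
        cx, cy = center
        to = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
        back = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=float)
        R = back @ R @ to
    T = np.array([[1, 0, tx], [0, 1, ty], [0, 0, 1]], dtype=float)
    return normalize_homography(T @ R)


def apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Map ``(n, 2)`` points ``(x, y)`` through ``H``."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    ones = np.ones((pts.shape[0], 1))
    ph = np.hstack([pts, ones]) @ np.asarray(H, dtype=float).T
    return ph[:, :2] / ph[:, 2:3]


def is_identity(H: np.ndarray, atol: float = 1e-12) -> bool:
    return np.allclose(np.asarray(H, dtype=float), np.eye(3), atol=atol)


def corner_error(H_est: np.ndarray, H_true: np.ndarray, shape: tuple[int, int]) -> float:
    """Maximum displacement (px) between the two mappings over the four frame
    corners of a ``(height, width)`` frame."""
    h, w = shape
    corners = np.array([[0, 0], [w - 1.0, 0], [0, h - 1.0], [w - 1.0, h - 1.0]])
    d = apply_homography(H_est, corners) - apply_homography(H_true, corners)
    return float(np.linalg.norm(d, axis=1).max())
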