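"""Local coordinate frames, relative quaternions, and distance encodings.

Residue- and atom-level geometry is expressed through right-handed
orthonormal local frames. Relative positions and orientations computed
in these frames are invariant under any global rigid motion of the
structure, which is the property that makes the downstream graph
features pose-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

__all__ = [
    "LocalFrame",
    "gram_schmidt_frame",
    "fallback_frame",
    "relative_rotation",
    "relative_quaternion",
    "canonical_quaternion",
    "local_coordinates",
    "rbf",
]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class LocalFrame:
    """A right-handed orthonormal frame: origin plus basis rows x̂, ŷ, ẑ."""

    origin: np.ndarray  # (3,) Å
    basis: np.ndarray   # (3, 3), rows are the unit axes

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=np.float64))
        object.__setattr__(self, "basis", np.asarray(self.basis, dtype=np.float64))

    def is_orthonormal(self, tol: float = _ORTHO_TOL) -> bool:
        b = self.basis
        return (np.allclose(b @ b.T, np.eye(3), atol=tol)
                and abs(np.linalg.det(b) - 1.0) <= tol)


def _normalize(v: np.ndarray) -> np.ndarray | None:
    n = np.linalg.norm(v)
    if n < 1e-8:
        return None
    return v / n


def gram_schmidt_frame(origin: np.ndarray, primary: np.ndarray,
                       secondary: np.ndarray) -> LocalFrame | None:
    """Frame with x̂ along ``primary`` and ŷ the orthogonalized ``secondary``.

    Returns None when the two directions are degenerate (zero or collinear).
    """
    x = _normalize(np.asarray(primary, dtype=np.float64))
    if x is None:
        return None
    s = np.asarray(secondary, dtype=np.float64)
    y = _normalize(s - np.dot(s, x) * x)
    if y is None:
        return None
    z = np.cross(x, y)
    return LocalFrame(origin=np.asarray(origin, dtype=np.float64),
                      basis=np.stack([x, y, z]))


def fallback_frame(origin: np.ndarray, primary: np.ndarray) -> LocalFrame:
    """Complete a frame from a single direction by Gram–Schmidt against a
    global axis (+z, or +x when ``primary`` is parallel to +z)."""
    frame = gram_schmidt_frame(origin, primary, np.array([0.0, 0.0, 1.0]))
    if frame is None:
        frame = gram_schmidt_frame(origin, primary, np.array([1.0, 0.0, 0.0]))
    if frame is None:  # primary itself degenerate: identity basis
        frame = LocalFrame(origin=origin, basis=np.eye(3))
    return frame


def relative_rotation(frame_i: LocalFrame, frame_j: LocalFrame) -> np.ndarray:
    """Rotation matrix relating two frames, R[a, b] = axis_a(i)·axis_b(j).

    Computed purely from inner products of the two bases, so it is
    unchanged when both frames co-rotate under a global rigid motion.
    """
    return frame_i.basis @ frame_j.basis.T


def canonical_quaternion(q: np.ndarray) -> np.ndarray:
    """Fix the double-cover sign: w ≥ 0; if w == 0, first nonzero of
    (x, y, z) positive."""
    q = np.asarray(q, dtype=np.float64)
    w = q[0]
    if w < -1e-12:
        return -q
    if abs(w) <= 1e-12:
        for c in q[1:]:
            if abs(c) > 1e-12:
                return q if c > 0 else -q
    return q


def relative_quaternion(frame_i: LocalFrame, frame_j: LocalFrame) -> np.ndarray:
    """Unit quaternion (w, x, y, z) for the rotation between two frames.

    Raises ValueError if either frame is not orthonormal.
    """
    for name, f in (("frame_i", frame_i), ("frame_j", frame_j)):
        if not f.is_orthonormal(tol=1e-5):
            raise ValueError(f"{name} is not an orthonormal right-handed frame")
    rot = relative_rotation(frame_i, frame_j)
    xyzw = Rotation.from_matrix(rot).as_quat()  # scipy order (x, y, z, w)
    q = np.array([xyzw[3], xyzw[0], xyzw[1], xyzw[2]])
    q /= np.linalg.norm(q)
    return canonical_quaternion(q)


def local_coordinates(frame: LocalFrame, point: np.ndarray) -> np.ndarray:
    """Coordinates of ``point`` expressed in ``frame``."""
    return frame.basis @ (np.asarray(point, dtype=np.float64) - frame.origin)


def rbf(distance, sigma: float = 1.0):
    """Gaussian radial basis encoding φ(d) = exp(−d² / 2σ²) ∈ (0, 1]."""
    d = np.asarray(distance, dtype=np.float64)
    return np.exp(-(d * d) / (2.0 * sigma * sigma))
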