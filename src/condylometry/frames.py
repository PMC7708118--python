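"""Anatomical reference frame built from skull landmarks.

The frame convention used throughout the package is right-handed with

* ``z`` — cranial, the Frankfurt Horizontal (FH) plane is ``z = 0``;
* ``x`` — toward the anatomical left, the midsagittal plane (MSP) is ``x = 0``;
* ``y`` — anterior.

The FH plane is fitted to the two porions and the (left) orbitale; the MSP
is orthogonal to FH, passes through nasion, and has its normal along the
porion–porion direction projected into FH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateFrameError, LandmarkError

#: landmark names required to construct the frame
FRAME_LANDMARKS = ("porion_left", "porion_right", "orbitale", "nasion")

_EPS = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _EPS:
        raise DegenerateFrameError("zero-length direction while building frame")
    return v / n


@dataclass(frozen=True)
class ReferenceFrame:
    """Orthonormal right-handed anatomical frame.

    Attributes
    ----------
    origin : (3,) array
        World point on both the FH plane and the MSP.
    msp_normal : (3,) array
        Unit normal of the midsagittal plane, pointing toward the left.
    anterior : (3,) array
        Unit vector pointing anteriorly, lying in the FH plane.
    fh_normal : (3,) array
        Unit normal of the Frankfurt Horizontal plane, pointing cranially.
    """

    origin: np.ndarray
    msp_normal: np.ndarray
    anterior: np.ndarray
    fh_normal: np.ndarray

    def __post_init__(self) -> None:
        R = np.column_stack([self.msp_normal, self.anterior, self.fh_normal])
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise DegenerateFrameError("frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise DegenerateFrameError("frame axes are not right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """World-from-frame rotation matrix (columns = frame axes)."""
        return np.column_stack([self.msp_normal, self.anterior, self.fh_normal])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates into frame coordinates ``(x, y, z)``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.origin) @ self.rotation
        return out[0] if np.asarray(points).ndim == 1 else out

    def to_world(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.origin
        return out[0] if np.asarray(points).ndim == 1 else out

    @staticmethod
    def identity() -> "ReferenceFrame":
        return ReferenceFrame(
            origin=np.zeros(3),
            msp_normal=np.array([1.0, 0.0, 0.0]),
            anterior=np.array([0.0, 1.0, 0.0]),
            fh_normal=np.array([0.0, 0.0, 1.0]),
        )


def build_reference_frame(landmarks: dict) -> ReferenceFrame:
    """Construct the FH/MSP frame from porions, orbitale and nasion.

    Parameters
    ----------
    landmarks : dict
        Mapping of landmark name to a length-3 coordinate. Must contain
        ``porion_left``, ``porion_right``, ``orbitale`` and ``nasion``.

    Raises
    ------
    LandmarkError
        If a required landmark is absent.
    DegenerateFrameError
        If the landmarks are coincident or collinear.
    """
    try:
        po_l = np.asarray(landmarks["porion_left"], dtype=float)
        po_r = np.asarray(landmarks["porion_right"], dtype=float)
        orb = np.asarray(landmarks["orbitale"], dtype=float)
        nas = np.asarray(landmarks["nasion"], dtype=float)
    except KeyError as exc:  # pragma: no cover - message formatting
        raise LandmarkError(f"missing frame landmark: {exc.args[0]}") from exc

    ear_axis = po_l - po_r
    if np.linalg.norm(ear_axis) < 1e-6:
        raise DegenerateFrameError("porions are coincident")
    # FH plane through both porions and the orbitale
    v2 = orb - po_r
    normal = np.cross(ear_axis, v2)
    if np.linalg.norm(normal) < 1e-6:
        raise DegenerateFrameError("porions and orbitale are collinear")
    fh_normal = _unit(normal)
    # orient cranially: nasion lies above FH in any sane data set; fall back
    # to making the frame right-handed with left = porion_left side.
    centroid = (po_l + po_r + orb) / 3.0
    if np.dot(fh_normal, nas - centroid) < 0:
        fh_normal = -fh_normal

    # MSP normal: ear axis projected into FH, pointing left
    msp_normal = ear_axis - np.dot(ear_axis, fh_normal) * fh_normal
    if np.linalg.norm(msp_normal) < 1e-6:
        raise DegenerateFrameError("ear axis is parallel to the FH normal")
    msp_normal = _unit(msp_normal)

    anterior = np.cross(fh_normal, msp_normal)  # y = z × x, right-handed

    # origin: nasion projected into the FH plane (lies on the MSP by
    # construction, since the MSP passes through nasion with normal ⊥ z)
    origin = nas - np.dot(nas - centroid, fh_normal) * fh_normal
    return ReferenceFrame(origin=origin, msp_normal=msp_normal,
                          anterior=anterior, fh_normal=fh_normal)
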