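"""Cephalometric grouping variables and per-subject analysis variables.

Three skeletal grouping variables are computed from landmarks:

* **menton deviation (Me-MSP)** — signed perpendicular distance of menton
  from the midsagittal plane (positive toward the left); classifies
  transversal symmetry (symmetric < 2 mm, moderate 2–4 mm, strong > 4 mm);
* **Wits appraisal** — distance between the perpendicular projections of
  points A and B onto the occlusal plane, measured along the anterior
  direction (positive = A ahead of B); classifies the sagittal relation
  (Class I in [−2, 2] mm, Class II > 2 mm, Class III < −2 mm);
* **ML-NL angle** — angle between the mandibular line (mid-Gonion to
  menton) and the nasal line (ANS to PNS), both projected onto the MSP;
  classifies the vertical relation (neutral in [20.5°, 26.5°],
  hypodivergent below, hyperdivergent above).

Bracketed class intervals are closed; the open-ended classes strict, as
printed. For the asymmetry analysis, each measurand's side difference is
the value on the side menton deviates *to* minus the value on the side it
deviates *from*; for the sagittal/vertical analyses the sides are averaged
(the volume ratio summed) per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import DegenerateFrameError, LandmarkError, UndefinedAngleError
from .frames import ReferenceFrame

SYMMETRY_THRESHOLDS = (2.0, 4.0)     # mm on |Me-MSP|
WITS_THRESHOLDS = (-2.0, 2.0)        # mm
MLNL_THRESHOLDS = (20.5, 26.5)       # degrees

AGGREGATE_VARIABLES = ("c_depth", "c_width", "c_height",
                       "c_incl_ap", "c_incl_ml", "ratio")


@dataclass(frozen=True)
class SkeletalClassification:
    """Grouping variables and class labels of one subject."""

    me_msp: float
    symmetry: str
    deviation_side: str
    wits: float
    sagittal: str
    ml_nl: float
    vertical: str


def _get(landmarks: Mapping, name: str) -> np.ndarray:
    try:
        p = np.asarray(landmarks[name], dtype=float)
    except KeyError as exc:
        raise LandmarkError(f"missing landmark: {name}") from exc
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise LandmarkError(f"landmark {name} must be a finite 3-vector")
    return p


def menton_deviation(landmarks: Mapping, frame: ReferenceFrame) -> tuple:
    """Signed Me-MSP distance (mm, + = left) and the deviation side.

    A menton exactly on the MSP is assigned to the right side by
    convention (this only affects the sign of Diff variables for
    perfectly symmetric subjects).
    """
    me = frame.to_frame(_get(landmarks, "Me"))
    me_msp = float(me[0])
    side = "left" if me_msp > 0 else "right"
    return me_msp, side


def wits_appraisal(landmarks: Mapping, frame: ReferenceFrame) -> float:
    """Wits appraisal (mm): A- and B-point projections onto the
    least-squares occlusal plane, separated along the anterior direction."""
    a_pt = frame.to_frame(_get(landmarks, "A"))
    b_pt = frame.to_frame(_get(landmarks, "B"))
    occ = [frame.to_frame(_get(landmarks, name)) for name in sorted(landmarks)
           if name.startswith("occlusal")]
    if len(occ) < 3:
        raise LandmarkError("Wits appraisal needs at least 3 occlusal points")
    occ = np.asarray(occ)
    centroid = occ.mean(axis=0)
    # least-squares plane: smallest principal direction of the point cloud
    u, s, vt = np.linalg.svd(occ - centroid)
    if s[1] < 1e-8:
        raise DegenerateFrameError("occlusal points are collinear; cannot "
                                   "fit a plane")
    normal = vt[2]
    anterior = np.array([0.0, 1.0, 0.0]) - normal[1] * normal
    n_ant = np.linalg.norm(anterior)
    if n_ant < 1e-8:
        raise DegenerateFrameError("occlusal plane is orthogonal to the "
                                   "anterior direction")
    anterior /= n_ant

    def project(p):
        return p - np.dot(p - centroid, normal) * normal

    return float(np.dot(project(a_pt) - project(b_pt), anterior))


def ml_nl_angle(landmarks: Mapping, frame: ReferenceFrame) -> float:
    """Maxillomandibular plane angle (degrees, in [0, 90)).

    The mandibular line runs from the Gonion midpoint (either side alone
    if only one is given) to menton; the nasal line from ANS to PNS. Both
    are projected onto the midsagittal plane before taking the angle.
    """
    me = frame.to_frame(_get(landmarks, "Me"))
    ans = frame.to_frame(_get(landmarks, "ANS"))
    pns = frame.to_frame(_get(landmarks, "PNS"))
    gos = [frame.to_frame(_get(landmarks, n)) for n in ("Go_left", "Go_right")
           if n in landmarks]
    if not gos:
        raise LandmarkError("missing landmark: Go_left or Go_right")
    go = np.mean(gos, axis=0)
    ml = (me - go)[1:]      # project onto MSP: keep (y, z)
    nl = (pns - ans)[1:]
    if np.linalg.norm(ml) < 1e-9 or np.linalg.norm(nl) < 1e-9:
        raise UndefinedAngleError("degenerate mandibular or nasal line")
    cosang = abs(np.dot(ml, nl)) / (np.linalg.norm(ml) * np.linalg.norm(nl))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def classify_subject(me_msp: float, wits: float,
                     ml_nl: float) -> SkeletalClassification:
    """Assign the transversal, sagittal and vertical class labels."""
    for v in (me_msp, wits, ml_nl):
        if not np.isfinite(v):
            raise ValueError("grouping variables must be finite")
    dev = abs(me_msp)
    if dev < SYMMETRY_THRESHOLDS[0]:
        symmetry = "symmetric"
    elif dev <= SYMMETRY_THRESHOLDS[1]:
        symmetry = "moderate"
    else:
        symmetry = "strong"
    if WITS_THRESHOLDS[0] <= wits <= WITS_THRESHOLDS[1]:
        sagittal = "I"
    elif wits > WITS_THRESHOLDS[1]:
        sagittal = "II"
    else:
        sagittal = "III"
    if MLNL_THRESHOLDS[0] <= ml_nl <= MLNL_THRESHOLDS[1]:
        vertical = "neutral"
    elif ml_nl < MLNL_THRESHOLDS[0]:
        vertical = "hypodivergent"
    else:
        vertical = "hyperdivergent"
    return SkeletalClassification(
        me_msp=float(me_msp), symmetry=symmetry,
        deviation_side="left" if me_msp > 0 else "right",
        wits=float(wits), sagittal=sagittal,
        ml_nl=float(ml_nl), vertical=vertical)


def classify_from_landmarks(landmarks: Mapping,
                            frame: ReferenceFrame) -> SkeletalClassification:
    me_msp, _ = menton_deviation(landmarks, frame)
    return classify_subject(me_msp, wits_appraisal(landmarks, frame),
                            ml_nl_angle(landmarks, frame))


def side_differences(left: Mapping, right: Mapping,
                     deviation_side: str) -> dict:
    """Deviation-side minus non-deviation-side differences.

    ``left`` / ``right`` map the six variable names (``c_depth`` …
    ``ratio``) to values; flipping ``deviation_side`` negates every
    difference exactly.
    """
    if deviation_side not in ("left", "right"):
        raise ValueError("deviation_side must be 'left' or 'right'")
    dev, other = (left, right) if deviation_side == "left" else (right, left)
    out = {}
    for var in AGGREGATE_VARIABLES:
        if var not in dev or var not in other:
            raise LandmarkError(f"missing side value for variable {var!r}")
        out[f"diff_{var}"] = float(dev[var]) - float(other[var])
    return out


def subject_aggregate(left: Mapping, right: Mapping,
                      mand_volume: float) -> dict:
    """Per-subject aggregates: five measurands averaged over sides; the
    volume ratio computed from the *summed* condylar volumes."""
    if mand_volume <= 0:
        raise ValueError("mandibular volume must be positive")
    out = {}
    for var in AGGREGATE_VARIABLES[:-1]:
        if var not in left or var not in right:
            raise LandmarkError(f"missing side value for variable {var!r}")
        out[var] = (float(left[var]) + float(right[var])) / 2.0
    if "c_volume" not in left or "c_volume" not in right:
        raise LandmarkError("missing side value for variable 'c_volume'")
    out["ratio"] = 100.0 * (float(left["c_volume"])
                            + float(right["c_volume"])) / float(mand_volume)
    return out
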