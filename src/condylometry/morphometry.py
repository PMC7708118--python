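"""Condylar and mandibular measurements on triangle meshes.

All operations work in the anatomical frame defined by
:class:`~condylometry.frames.ReferenceFrame` (FH plane ``z = 0``, cranial
``+z``; MSP ``x = 0``, left ``+x``; anterior ``+y``). The measurands are:

``c_depth``
    distance between the most posterior and most anterior points of the
    condylar head (caliper distance by default; an axis-extent variant is
    available via ``depth_variant="extent"``);
``c_width``
    distance between the most lateral and most medial points;
``c_height``
    vertical distance from the most cranial point to the cut plane through
    the most caudal point of the mandibular (sigmoid) notch;
``c_incl_ap``
    angle between the FH plane and the cranial–posterior chord, measured
    after projecting both points onto the midsagittal plane;
``c_incl_ml``
    angle between the MSP and the medial–lateral chord, measured after
    projecting both points onto the FH plane;
``c_volume``
    enclosed volume of the condylar head above the notch plane;
``mand_volume`` and the percentage ratio ``100·C/Mand``.

The condylar head is the connected component of the side's mesh above the
notch plane that contains the most posterior point; connectivity excludes
the coronoid process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh

from .errors import (
    NoCondyleError,
    NotchDetectionError,
    UndefinedAngleError,
    VolumeError,
)
from .frames import ReferenceFrame, build_reference_frame

SIDES = ("left", "right")

#: nudge applied to cut planes so faces exactly coplanar with the cut do
#: not produce degenerate slivers below the vertex-merge tolerance;
#: far below every stated measurement tolerance
_CUT_EPS = 1e-3


@dataclass(frozen=True)
class CondylarMetrics:
    """The six per-side condylar measurands (mm / degrees / mm³)."""

    c_depth: float
    c_width: float
    c_height: float
    c_incl_ap: float
    c_incl_ml: float
    c_volume: float

    def as_dict(self) -> dict:
        return {
            "c_depth": self.c_depth, "c_width": self.c_width,
            "c_height": self.c_height, "c_incl_ap": self.c_incl_ap,
            "c_incl_ml": self.c_incl_ml, "c_volume": self.c_volume,
        }


@dataclass(frozen=True)
class MandibleMetrics:
    """Whole-mandible volume and condyle/mandible percentage ratios."""

    mand_volume: float
    ratio_left: float
    ratio_right: float
    ratio_summed: float


@dataclass
class CondylarHeadRegion:
    """A side's condylar head clipped above the notch plane."""

    side: str
    submesh: trimesh.Trimesh
    cut_height: float


# ---------------------------------------------------------------------------
# clipping and region extraction

def _boundary_loops(mesh: trimesh.Trimesh) -> list:
    """Directed boundary loops (vertex index sequences) of an open mesh."""
    edges = mesh.edges  # directed, per face winding
    edges_sorted = np.sort(edges, axis=1)
    _, inverse, counts = np.unique(edges_sorted, axis=0,
                                   return_inverse=True, return_counts=True)
    boundary = edges[counts[inverse] == 1]
    nxt = {int(a): int(b) for a, b in boundary}
    loops = []
    while nxt:
        start, cur = next(iter(nxt.items()))
        loop = [start]
        while cur != start:
            loop.append(cur)
            cur = nxt.pop(cur, None)
            if cur is None:
                raise VolumeError("open, non-loop boundary after clipping")
        nxt.pop(start, None)
        loops.append(loop)
    return loops


def _ear_clip(poly: np.ndarray) -> list:
    """Triangulate a simple 2D polygon (CCW) by ear clipping; returns
    index triples into ``poly``."""
    n = len(poly)
    if n < 3:
        return []
    idx = list(range(n))
    tris = []
    guard = 0
    while len(idx) > 3 and guard < 4 * n * n:
        guard += 1
        m = len(idx)
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = poly[i0], poly[i1], poly[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-12:
                continue  # reflex or degenerate corner
            others = [j for j in idx if j not in (i0, i1, i2)]
            if others:
                P = poly[others]
                d1 = (b[0] - a[0]) * (P[:, 1] - a[1]) - (b[1] - a[1]) * (P[:, 0] - a[0])
                d2 = (c[0] - b[0]) * (P[:, 1] - b[1]) - (c[1] - b[1]) * (P[:, 0] - b[0])
                d3 = (a[0] - c[0]) * (P[:, 1] - c[1]) - (a[1] - c[1]) * (P[:, 0] - c[0])
                if np.any((d1 > -1e-12) & (d2 > -1e-12) & (d3 > -1e-12)):
                    continue  # another vertex inside the candidate ear
            tris.append((i0, i1, i2))
            idx.pop(k)
            break
        else:
            raise VolumeError("cap triangulation failed (degenerate cut "
                              "cross-section)")
    if len(idx) == 3:
        tris.append(tuple(idx))
    return tris


def _cap_boundary(mesh: trimesh.Trimesh, z: float) -> trimesh.Trimesh:
    """Close an upward region sliced at height ``z`` with planar caps."""
    loops = _boundary_loops(mesh)
    if not loops:
        return mesh
    V = mesh.vertices
    faces_new = []
    for loop in loops:
        pts = V[loop]
        if np.any(np.abs(pts[:, 2] - z) > 1e-4):
            raise VolumeError("clipped mesh has boundary away from the cut "
                              "plane; cannot cap")
        poly = pts[:, :2]
        # shoelace: ensure CCW for the ear clipper
        area2 = np.sum(poly[:, 0] * np.roll(poly[:, 1], -1)
                       - np.roll(poly[:, 0], -1) * poly[:, 1])
        order = loop if area2 > 0 else loop[::-1]
        poly = V[order][:, :2]
        for i0, i1, i2 in _ear_clip(poly):
            a, b, c = order[i0], order[i1], order[i2]
            # cap normal must point downward (outward for an upper region)
            faces_new.append([a, c, b])
    if not faces_new:
        return mesh
    out = trimesh.Trimesh(
        vertices=V.copy(),
        faces=np.vstack([mesh.faces, np.asarray(faces_new, int)]),
        process=False)
    return out


def clip_above(mesh: trimesh.Trimesh, z: float) -> trimesh.Trimesh:
    """Clip a watertight mesh by the horizontal plane ``z`` (keep above),
    capping the cut cross-sections so the result is watertight."""
    out = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=[0.0, 0.0, 1.0],
        plane_origin=[0.0, 0.0, z + _CUT_EPS], cap=False)
    if out is None or len(out.faces) == 0:
        return trimesh.Trimesh(vertices=np.zeros((0, 3)),
                               faces=np.zeros((0, 3), int))
    out.merge_vertices()  # slicing duplicates the new cut vertices per face
    out.update_faces(out.nondegenerate_faces())
    out.remove_unreferenced_vertices()
    out = _cap_boundary(out, z + _CUT_EPS)
    out.remove_unreferenced_vertices()
    return out


def notch_cut_plane(mesh: trimesh.Trimesh, frame: ReferenceFrame, side: str,
                    notch_landmark: Optional[np.ndarray] = None,
                    n_samples: int = 60) -> float:
    """z-level of the most caudal point of the mandibular notch.

    If ``notch_landmark`` (world coordinates) is given it is authoritative
    and simply transformed into the frame. Otherwise the sigmoid notch is
    detected from the mesh silhouette in the sagittal view: the upper
    envelope of the side's cross-sections must show two peaks (condylar and
    coronoid processes); the notch level is the envelope minimum between
    them.

    Raises
    ------
    NotchDetectionError
        If fewer than two processes are found (e.g. a sphere).
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    if notch_landmark is not None:
        return float(frame.to_frame(np.asarray(notch_landmark, float))[2])

    from scipy.signal import find_peaks

    verts = frame.to_frame(mesh.vertices)
    sign = 1.0 if side == "left" else -1.0
    side_verts = verts[sign * verts[:, 0] > 0]
    if len(side_verts) == 0:
        raise NotchDetectionError(f"no geometry on the {side} side")
    y_lo, y_hi = side_verts[:, 1].min(), side_verts[:, 1].max()
    pad = 1e-3 * max(1.0, y_hi - y_lo)
    ys = np.linspace(y_lo + pad, y_hi - pad, n_samples)

    mesh_f = mesh.copy()
    mesh_f.vertices = verts
    envelope, kept_y = [], []
    for y in ys:
        sec = mesh_f.section(plane_origin=[0.0, y, 0.0],
                             plane_normal=[0.0, 1.0, 0.0])
        if sec is None:
            continue
        pts = sec.vertices
        pts = pts[sign * pts[:, 0] > 0]
        if len(pts) == 0:
            continue
        envelope.append(pts[:, 2].max())
        kept_y.append(y)
    envelope = np.asarray(envelope)
    if len(envelope) < 5:
        raise NotchDetectionError(
            "too few silhouette samples; supply a notch landmark")
    peaks, _ = find_peaks(envelope, prominence=1.0)
    # end points can be maxima too (processes at the range limits)
    for edge in (0, len(envelope) - 1):
        if edge not in peaks:
            inner = envelope[1] if edge == 0 else envelope[-2]
            if envelope[edge] > inner + 0.5:
                peaks = np.sort(np.append(peaks, edge))
    if len(peaks) < 2:
        raise NotchDetectionError(
            "could not find two processes (condylar and coronoid) in the "
            "sagittal silhouette; supply a notch landmark instead")
    # the two tallest peaks bound the notch
    order = peaks[np.argsort(envelope[peaks])[::-1][:2]]
    i, j = sorted(order)
    if j - i < 2:
        raise NotchDetectionError(
            "processes are not separated by a notch; supply a landmark")
    return float(envelope[i + 1:j].min())


def extract_condylar_head(mesh: trimesh.Trimesh, frame: ReferenceFrame,
                          side: str, cut_height: float) -> CondylarHeadRegion:
    """Clip the mandible above ``cut_height`` and isolate the condylar head.

    The returned region is the connected component on the requested side
    (sign of frame ``x``) that contains the most posterior point of that
    side's clipped geometry; the coronoid process, lying anteriorly, is a
    separate component and is excluded.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    if not mesh.is_watertight:
        raise VolumeError("condylar extraction requires a watertight mesh")
    mesh_f = mesh.copy()
    mesh_f.vertices = frame.to_frame(mesh.vertices)
    clipped = clip_above(mesh_f, cut_height)
    if clipped.is_empty or len(clipped.faces) == 0:
        raise NoCondyleError(f"nothing above z={cut_height:g} on {side}")
    sign = 1.0 if side == "left" else -1.0
    comps = [c for c in clipped.split(only_watertight=False)
             if sign * c.vertices[:, 0].mean() > 0]
    if not comps:
        raise NoCondyleError(f"no {side}-side region above z={cut_height:g}")
    # component containing the most posterior (smallest y) vertex
    y_mins = [c.vertices[:, 1].min() for c in comps]
    region = comps[int(np.argmin(y_mins))]
    return CondylarHeadRegion(side=side, submesh=region, cut_height=cut_height)


# ---------------------------------------------------------------------------
# point-wise measurands

def extreme_point(region: CondylarHeadRegion, direction: np.ndarray) -> np.ndarray:
    """Vertex of the region maximizing the dot product with ``direction``.

    Ties are broken deterministically by larger z, then larger y, then
    larger x, so the result is independent of vertex ordering.
    """
    V = region.submesh.vertices
    if len(V) == 0:
        raise NoCondyleError("empty condylar region")
    d = V @ np.asarray(direction, float)
    idx = np.lexsort((V[:, 0], V[:, 1], V[:, 2], d))[-1]
    return V[idx].copy()


def condylar_linear_metrics(region: CondylarHeadRegion,
                            depth_variant: str = "caliper") -> tuple:
    """(c_depth, c_width, c_height) of a condylar head region.

    ``depth_variant="caliper"`` measures point-to-point distances between
    the extreme vertices (the default, matching manual landmark tools);
    ``"extent"`` measures axis-aligned extents instead.
    """
    if depth_variant not in ("caliper", "extent"):
        raise ValueError("depth_variant must be 'caliper' or 'extent'")
    p_ant = extreme_point(region, [0, 1, 0])
    p_post = extreme_point(region, [0, -1, 0])
    p_lat_pos = extreme_point(region, [1, 0, 0])
    p_lat_neg = extreme_point(region, [-1, 0, 0])
    p_cran = extreme_point(region, [0, 0, 1])
    if depth_variant == "caliper":
        c_depth = float(np.linalg.norm(p_ant - p_post))
        c_width = float(np.linalg.norm(p_lat_pos - p_lat_neg))
    else:
        c_depth = float(p_ant[1] - p_post[1])
        c_width = float(p_lat_pos[0] - p_lat_neg[0])
    c_height = float(p_cran[2] - region.cut_height)
    return c_depth, c_width, c_height


def condylar_inclinations(region: CondylarHeadRegion) -> tuple:
    """(c_incl_ap, c_incl_ml) in degrees, both unsigned in [0, 90].

    The antero-posterior inclination is the angle between the FH plane and
    the cranial–posterior chord viewed in the midsagittal plane; the
    medio-lateral inclination is the angle between the MSP and the
    medial–lateral chord viewed in the FH (axial) plane.
    """
    p_cran = extreme_point(region, [0, 0, 1])
    p_post = extreme_point(region, [0, -1, 0])
    v = p_cran - p_post
    if abs(v[1]) < 1e-12 and abs(v[2]) < 1e-12:
        raise UndefinedAngleError("cranial and posterior points coincide in MSP")
    incl_ap = float(np.degrees(np.arctan2(abs(v[2]), abs(v[1]))))

    p_lat = extreme_point(region, [1, 0, 0])
    p_med = extreme_point(region, [-1, 0, 0])
    w = p_lat - p_med
    if abs(w[0]) < 1e-12 and abs(w[1]) < 1e-12:
        raise UndefinedAngleError("medial and lateral points coincide in FH")
    incl_ml = float(np.degrees(np.arctan2(abs(w[0]), abs(w[1]))))
    return incl_ap, incl_ml


def clipped_volume(region: CondylarHeadRegion) -> float:
    """Enclosed volume (mm³) of the capped condylar region."""
    sub = region.submesh
    if not sub.is_watertight:
        raise VolumeError("condylar region is not watertight; cannot "
                          "compute an enclosed volume")
    return float(abs(sub.volume))


def volume_ratio(c_left: float, c_right: float,
                 mand_volume: float) -> MandibleMetrics:
    """Per-side and summed condyle/mandible percentage ratios."""
    if not mand_volume > 0:
        raise VolumeError("mandibular volume must be positive")
    return MandibleMetrics(
        mand_volume=float(mand_volume),
        ratio_left=100.0 * c_left / mand_volume,
        ratio_right=100.0 * c_right / mand_volume,
        ratio_summed=100.0 * (c_left + c_right) / mand_volume,
    )


# ---------------------------------------------------------------------------
# convenience: full per-subject measurement

def measure_mandible(mesh: trimesh.Trimesh, landmarks: dict,
                     depth_variant: str = "caliper") -> dict:
    """Measure both condyles and the mandibular volume of one subject.

    ``landmarks`` must contain the frame landmarks; optional
    ``notch_left`` / ``notch_right`` entries are used as the notch cut
    points, otherwise the notch is auto-detected from the silhouette.

    Returns a dict with keys ``left`` and ``right``
    (:class:`CondylarMetrics`), ``mandible`` (:class:`MandibleMetrics`),
    ``frame`` and per-side ``cut_height``.
    """
    frame = build_reference_frame(landmarks)
    if not mesh.is_watertight:
        raise VolumeError("mandible mesh is not watertight")
    mand_volume = float(abs(mesh.volume))
    per_side = {}
    cuts = {}
    for side in SIDES:
        lm = landmarks.get(f"notch_{side}")
        cut = notch_cut_plane(mesh, frame, side, notch_landmark=lm)
        region = extract_condylar_head(mesh, frame, side, cut)
        d, w, h = condylar_linear_metrics(region, depth_variant=depth_variant)
        ap, ml = condylar_inclinations(region)
        vol = clipped_volume(region)
        per_side[side] = CondylarMetrics(
            c_depth=d, c_width=w, c_height=h,
            c_incl_ap=ap, c_incl_ml=ml, c_volume=vol)
        cuts[side] = cut
    mand = volume_ratio(per_side["left"].c_volume,
                        per_side["right"].c_volume, mand_volume)
    return {"left": per_side["left"], "right": per_side["right"],
            "mandible": mand, "frame": frame, "cut_height": cuts}
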