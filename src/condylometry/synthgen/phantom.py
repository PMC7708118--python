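"""Parametric mandible phantoms with closed-form ground truth.

The phantom is deliberately schematic rather than anatomical: every part
is a primitive with an exact volume so that all morphometric quantities
have closed forms. Per side it consists of

* an ellipsoidal condylar head (semiaxes = ``head_semiaxes``, optionally
  tilted by a rigid rotation about its centre),
* a lofted neck joining the head's cross-section at the junction plane to
  a small elliptical base on the ramus top,
* a conical coronoid process anterior to the condyle,
* a box ramus, and a shared box body whose lower front edge carries the
  menton landmark.

The ramus top between the two processes is flat; its level is the most
caudal point of the sigmoid notch and therefore the condylar cut plane.
The head tilt is solved so that the analytically achieved antero-posterior
and medio-lateral inclination angles (read from the rotation via the
ellipsoid extreme-point formulas) equal the requested angles exactly.

Everything is built directly in the anatomical frame (FH ``z = 0``, MSP
``x = 0``, ``+x`` left, ``+y`` anterior); the landmark set returned allows
the measurement pipeline to reconstruct that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import trimesh
from scipy.optimize import brentq

from ..errors import PhantomError, SpecValidationError
from ..morphometry import CondylarMetrics

# fixed layout constants (mm, anatomical frame)
Z_NOTCH = -15.0            # sigmoid-notch plane (ramus top)
RAMUS_X = (35.0, 49.0)     # left ramus x-range; right side mirrored
RAMUS_Y = (6.0, 31.0)
BODY_X = (-50.0, 50.0)
BODY_Y = (5.0, 70.0)
CONDYLE_CENTER_XY = (42.0, 12.0)
CONDYLE_BASE_SEMI = (5.0, 3.0)
CORONOID_CENTER_XY = (42.0, 26.0)
CORONOID_BASE_SEMI = (4.0, 3.0)
JUNCTION_LEVEL = -0.75     # junction plane position in head-sphere coords
Z_OCCLUSAL = -45.0
Z_NASAL_LINE = -30.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic mandible phantom.

    ``head_semiaxes`` are the condylar head's (medio-lateral,
    antero-posterior, cranio-caudal) semiaxes in mm. ``incl_ap_deg`` /
    ``incl_ml_deg`` are the target inclination angles in degrees (``None``
    leaves the corresponding tilt at zero). ``menton_offset`` is signed,
    positive toward the anatomical left. ``wits_mm`` and ``ml_nl_deg``
    place the cephalometric landmarks. ``mesh_resolution`` controls ring
    and segment counts (``4·2^r`` azimuthal segments).
    """

    head_semiaxes: tuple = (10.0, 4.0, 8.0)
    incl_ap_deg: Optional[float] = 52.0
    incl_ml_deg: Optional[float] = 67.0
    ramus_height: float = 40.0
    notch_depth: float = 10.0
    menton_offset: float = 0.0
    wits_mm: float = -0.8
    ml_nl_deg: float = 23.2
    neck_height: float = 6.0
    mesh_resolution: int = 4
    seed: int = 0

    def validate(self) -> None:
        a, b, c = self.head_semiaxes
        if not (a > 0 and b > 0 and c > 0):
            raise SpecValidationError("head semiaxes must be positive")
        for ang in (self.incl_ap_deg, self.incl_ml_deg):
            if ang is not None and not (0.0 <= ang < 90.0):
                raise SpecValidationError("inclination targets must be in [0, 90)")
        if self.ramus_height <= 0 or self.notch_depth <= 0 or self.neck_height <= 0:
            raise SpecValidationError("heights must be positive")
        if not (2.0 <= self.ml_nl_deg <= 50.0):
            raise SpecValidationError("ml_nl_deg must be in [2, 50] degrees")
        if abs(self.menton_offset) > 45.0:
            raise SpecValidationError("menton offset must be within ±45 mm")
        if not (1 <= int(self.mesh_resolution) <= 7):
            raise SpecValidationError("mesh_resolution must be in 1..7")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form measurands implied by a :class:`PhantomSpec`."""

    left: CondylarMetrics
    right: CondylarMetrics
    mand_volume: float
    ratio_per_side: float
    ratio_summed: float
    me_msp: float
    wits: float
    ml_nl: float
    notch_z: float


# ---------------------------------------------------------------------------
# head rotation

def _rot_x(phi):
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(psi):
    c, s = np.cos(psi), np.sin(psi)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _achieved_angles(R: np.ndarray, D2: np.ndarray) -> tuple:
    """(incl_ap, incl_ml) in degrees implied by rotation R for an
    ellipsoid with squared-semiaxis diagonal D2, via the extreme-point
    chord formulas."""
    M = R @ D2 @ R.T
    # medio-lateral chord = M e_x, projected on FH, angle to the MSP trace
    dx, dy = M[0, 0], M[1, 0]
    incl_ml = np.degrees(np.arctan2(abs(dx), abs(dy)))
    # cranial and posterior extreme points; chord projected on the MSP
    p_cr = M[:, 2] / np.sqrt(M[2, 2])
    p_po = -M[:, 1] / np.sqrt(M[1, 1])
    v = p_cr - p_po
    incl_ap = np.degrees(np.arctan2(abs(v[2]), abs(v[1])))
    return float(incl_ap), float(incl_ml)


def _first_crossing(f, grid):
    """First sign change of ``f`` along ``grid``, refined by brentq;
    None if no crossing exists."""
    prev_x, prev_v = grid[0], f(grid[0])
    if abs(prev_v) < 1e-11:
        return prev_x
    for x in grid[1:]:
        v = f(x)
        if abs(v) < 1e-11:
            return x
        if prev_v * v < 0:
            return brentq(f, prev_x, x, xtol=1e-13)
        prev_x, prev_v = x, v
    return None


def _solve_head_rotation(spec: PhantomSpec) -> np.ndarray:
    """Rigid head rotation whose implied inclinations equal the targets.

    Yaw about z mainly drives the medio-lateral angle and pitch about the
    head's long axis the antero-posterior one. With an anisotropic head
    the two angles interact and neither map is monotone, so the yaw is
    solved for the m-l target at each candidate pitch (first crossing from
    the untilted 90°) and the pitch bracketed by a scan.
    """
    a, b, c = spec.head_semiaxes
    D2 = np.diag([a * a, b * b, c * c])

    def rotation(psi, phi):
        return _rot_z(psi) @ _rot_x(phi)

    def solve_psi(phi):
        if spec.incl_ml_deg is None:
            return 0.0
        f = lambda psi: (_achieved_angles(rotation(psi, phi), D2)[1]
                         - spec.incl_ml_deg)
        psi = _first_crossing(f, np.radians(np.linspace(0.0, 89.0, 90)))
        if psi is None:
            raise SpecValidationError(
                f"incl_ml_deg={spec.incl_ml_deg} unreachable for head "
                f"semiaxes {spec.head_semiaxes}")
        return psi

    if spec.incl_ap_deg is None:
        return rotation(solve_psi(0.0), 0.0)

    def g(phi):
        psi = solve_psi(phi)
        return _achieved_angles(rotation(psi, phi), D2)[0] - spec.incl_ap_deg

    # prefer the smallest pitch: scan outward from zero
    phis = np.radians(np.concatenate([[0.0], np.repeat(
        np.linspace(2.5, 75.0, 30), 2) * np.tile([1, -1], 30)]))
    phi = _first_crossing_scan_pairs(g, phis)
    if phi is None:
        raise SpecValidationError(
            f"(incl_ap_deg, incl_ml_deg)=({spec.incl_ap_deg}, "
            f"{spec.incl_ml_deg}) unreachable for head semiaxes "
            f"{spec.head_semiaxes}")
    return rotation(solve_psi(phi), phi)


def _first_crossing_scan_pairs(g, phis):
    """Bracket a root of ``g`` scanning outward from phi=0 on both sides."""
    vals = {}

    def ev(x):
        if x not in vals:
            try:
                vals[x] = g(x)
            except SpecValidationError:
                vals[x] = None
        return vals[x]

    pos = [x for x in phis if x >= 0]
    neg = [0.0] + [x for x in phis if x < 0]
    for branch in (sorted(set(pos)), sorted(set(neg), reverse=True)):
        for lo, hi in zip(branch[:-1], branch[1:]):
            vlo, vhi = ev(lo), ev(hi)
            if vlo is None or vhi is None:
                continue
            if abs(vlo) < 1e-11:
                return lo
            if abs(vhi) < 1e-11:
                return hi
            if vlo * vhi < 0:
                return brentq(g, min(lo, hi), max(lo, hi), xtol=1e-13)
    return None


# ---------------------------------------------------------------------------
# mesh primitives

def _component(vertices, faces) -> trimesh.Trimesh:
    m = trimesh.Trimesh(vertices=np.asarray(vertices, float),
                        faces=np.asarray(faces, int), process=False)
    if m.volume < 0:
        m.invert()
    if not m.is_watertight:
        raise PhantomError("phantom component is not watertight "
                           "(generation bug)")
    return m


def _box(x0, x1, y0, y1, z0, z1) -> trimesh.Trimesh:
    m = trimesh.creation.box(extents=[x1 - x0, y1 - y0, z1 - z0])
    m.apply_translation([(x0 + x1) / 2, (y0 + y1) / 2, (z0 + z1) / 2])
    if not m.is_watertight:  # pragma: no cover - trimesh guarantees this
        raise PhantomError("box not watertight")
    return m


def _elliptic_cone(center_xy, semi, z0, height, n_seg) -> trimesh.Trimesh:
    cx, cy = center_xy
    sx, sy = semi
    th = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
    ring = np.column_stack([cx + sx * np.cos(th), cy + sy * np.sin(th),
                            np.full(n_seg, z0)])
    verts = np.vstack([[[cx, cy, z0]], ring, [[cx, cy, z0 + height]]])
    apex = n_seg + 1
    faces = []
    for i in range(n_seg):
        j = (i + 1) % n_seg
        faces.append([0, 1 + j, 1 + i])          # base disk, normal -z
        faces.append([1 + i, 1 + j, apex])       # flank
    return _component(verts, faces)


def _condylar_process(p0, A, base_center_xy, base_semi, z_notch, z_join,
                      n_seg, n_rings):
    """Watertight neck-loft + ellipsoid-cap component and its closed-form
    volume. ``A = R·diag(semiaxes)`` maps the unit sphere to the head."""
    t_hat = JUNCTION_LEVEL
    r = np.sqrt(1.0 - t_hat * t_hat)
    v = A.T @ np.array([0.0, 0.0, 1.0])          # plane normal in sphere coords
    vh = np.linalg.norm(v)                        # vertical half-extent
    v_hat = v / vh
    # consistency: junction plane z equals z_join given the head centre
    e1 = np.cross(v_hat, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(v_hat, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v_hat, e1)

    def junction_axes(e1, e2):
        A1 = r * (A @ e1)
        A2 = r * (A @ e2)
        return A1, A2

    A1, A2 = junction_axes(e1, e2)
    # match the base ring's winding (counter-clockwise seen from +z)
    if A1[0] * A2[1] - A1[1] * A2[0] < 0:
        e2 = -e2
        A1, A2 = junction_axes(e1, e2)
    # phase-align so the loft does not twist: shift the parameter so the
    # junction ring's theta=0 axis has zero y-component and positive x
    ph = np.arctan2(-A1[1], A2[1]) if (abs(A1[1]) + abs(A2[1])) > 0 else 0.0
    if A1[0] * np.cos(ph) + A2[0] * np.sin(ph) < 0:
        ph += np.pi
    e1, e2 = (np.cos(ph) * e1 + np.sin(ph) * e2,
              -np.sin(ph) * e1 + np.cos(ph) * e2)
    A1, A2 = junction_axes(e1, e2)

    alpha0 = np.arccos(t_hat)
    # sample the cap so the four lateral extreme points of the ellipsoid
    # (±x, ±y world directions) fall exactly on grid vertices: add their
    # polar/azimuthal coordinates to the ring and segment grids
    extra_polar, extra_theta = [], []
    for w in ([1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]):
        u_star = A.T @ np.asarray(w, float)
        u_star /= np.linalg.norm(u_star)
        polar = np.arccos(np.clip(u_star @ v_hat, -1, 1))
        if polar < alpha0 - 1e-9:
            extra_polar.append(polar)
            extra_theta.append(np.arctan2(u_star @ e2, u_star @ e1) % (2 * np.pi))

    def _merge_grid(grid, extras, period=None, tol=1e-3):
        # keep the exact extreme coordinates, dropping grid points that are
        # too close to them (near-duplicate vertices would later collapse
        # under vertex merging and open sliver holes)
        extras = np.asarray(extras, float)
        if len(extras) == 0:
            return np.sort(grid)
        extras = np.unique(extras)
        extras = np.concatenate([[extras[0]],
                                 extras[1:][np.diff(extras) > tol]])
        keep = []
        for gval in grid:
            d = np.abs(extras - gval)
            if period is not None:
                d = np.minimum(d, period - d)
            if np.all(d > tol):
                keep.append(gval)
        return np.sort(np.concatenate([keep, extras]))

    th = _merge_grid(np.linspace(0, 2 * np.pi, n_seg, endpoint=False),
                     extra_theta, period=2 * np.pi)
    n_th = len(th)
    cos_t, sin_t = np.cos(th), np.sin(th)

    polar_levels = _merge_grid(alpha0 * (1 - np.arange(n_rings) / n_rings),
                               extra_polar)[::-1]
    polar_levels = polar_levels[polar_levels > 1e-6]
    n_lev = len(polar_levels)

    bx, by = base_center_xy
    sbx, sby = base_semi
    base_ring = np.column_stack([bx + sbx * cos_t, by + sby * sin_t,
                                 np.full(n_th, z_notch)])
    center_j = p0 + t_hat * (A @ v_hat)
    if abs(center_j[2] - z_join) > 1e-9:
        raise PhantomError("junction plane inconsistent (generation bug)")

    def sphere_ring(phi_polar):
        u = (np.cos(phi_polar) * v_hat[None, :]
             + np.sin(phi_polar) * (np.outer(cos_t, e1) + np.outer(sin_t, e2)))
        return p0 + u @ A.T

    cap_rings = [sphere_ring(p) for p in polar_levels]
    pole = p0 + A @ v_hat

    # loft volume: cross-section area is quadratic in height fraction s
    B = np.array([[sbx, 0.0], [0.0, sby]])
    T = np.column_stack([A1[:2], A2[:2]])

    def det_s(s):
        L = (1 - s) * B + s * T
        d = np.linalg.det(L)
        if d <= 0:
            raise PhantomError("neck loft degenerates (twist); generation bug")
        return d

    h = z_join - z_notch
    loft_volume = h * np.pi * (det_s(0.0) + 4 * det_s(0.5) + det_s(1.0)) / 6.0
    abc = abs(np.linalg.det(A))
    cap_volume = abc * np.pi * (2.0 / 3.0 - t_hat + t_hat ** 3 / 3.0)

    # assemble: base centre, base ring, cap rings (ring 0 = junction), pole
    verts = [np.array([[bx, by, z_notch]]), base_ring] + cap_rings + [pole[None, :]]
    verts = np.vstack(verts)
    base0 = 1
    ring_start = [1 + n_th + k * n_th for k in range(n_lev)]
    pole_idx = len(verts) - 1
    faces = []
    for i in range(n_th):
        j = (i + 1) % n_th
        faces.append([0, base0 + j, base0 + i])                    # bottom disk
        b_i, b_j = base0 + i, base0 + j
        t_i, t_j = ring_start[0] + i, ring_start[0] + j
        faces += [[b_i, b_j, t_i], [b_j, t_j, t_i]]                # neck wall
        for k in range(n_lev - 1):
            l_i, l_j = ring_start[k] + i, ring_start[k] + j
            u_i, u_j = ring_start[k + 1] + i, ring_start[k + 1] + j
            faces += [[l_i, l_j, u_i], [l_j, u_j, u_i]]            # cap bands
        faces.append([ring_start[-1] + i, ring_start[-1] + j, pole_idx])
    return _component(verts, faces), loft_volume + cap_volume


def _mirror(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    m = mesh.copy()
    m.vertices = m.vertices * np.array([-1.0, 1.0, 1.0])
    m.faces = m.faces[:, ::-1]
    return m


# ---------------------------------------------------------------------------
# generator

def generate_mandible_phantom(spec: PhantomSpec):
    """Build the phantom mesh, its landmark set, and the ground truth.

    Returns ``(mesh, landmarks, ground_truth)``. The mesh is watertight
    (several closed components with disjoint interiors, so the enclosed
    volume is the sum of the parts); landmarks are given in world
    coordinates (identical to the anatomical frame by construction).
    """
    spec.validate()
    a, b, c = (float(s) for s in spec.head_semiaxes)
    R = _solve_head_rotation(spec)
    D2 = np.diag([a * a, b * b, c * c])
    M = R @ D2 @ R.T
    A = R @ np.diag([a, b, c])
    vh = float(np.sqrt(M[2, 2]))

    z_join = Z_NOTCH + spec.neck_height
    p0 = np.array([CONDYLE_CENTER_XY[0], CONDYLE_CENTER_XY[1],
                   z_join - JUNCTION_LEVEL * vh])

    # head extreme points (left side), all must lie on the free cap surface
    def extreme(u):
        u = np.asarray(u, float)
        return p0 + M @ u / np.sqrt(u @ M @ u)

    p_cran = extreme([0, 0, 1])
    p_post = extreme([0, -1, 0])
    p_ant = extreme([0, 1, 0])
    p_lat = extreme([1, 0, 0])
    p_med = extreme([-1, 0, 0])
    margin = z_join + 0.02 * vh
    for p in (p_post, p_ant, p_lat, p_med):
        if p[2] < margin:
            raise SpecValidationError(
                "head tilt so extreme that an extreme point falls below the "
                "neck junction; reduce the inclination targets")

    n_seg = 8 * 2 ** int(spec.mesh_resolution)
    n_rings = 4 * 2 ** int(spec.mesh_resolution)

    condyle_l, c_volume = _condylar_process(
        p0, A, CONDYLE_CENTER_XY, CONDYLE_BASE_SEMI, Z_NOTCH, z_join,
        n_seg, n_rings)

    z_body_top = Z_NOTCH - spec.ramus_height
    coronoid_l = _elliptic_cone(CORONOID_CENTER_XY, CORONOID_BASE_SEMI,
                                Z_NOTCH, spec.notch_depth, n_seg)
    cor_volume = (np.pi * CORONOID_BASE_SEMI[0] * CORONOID_BASE_SEMI[1]
                  * spec.notch_depth / 3.0)
    ramus_l = _box(*RAMUS_X, *RAMUS_Y, z_body_top, Z_NOTCH)
    ramus_volume = ((RAMUS_X[1] - RAMUS_X[0]) * (RAMUS_Y[1] - RAMUS_Y[0])
                    * spec.ramus_height)

    # body: its lower front edge carries menton; depth set by the ML-NL target
    go_mid_y = RAMUS_Y[0]
    me_y = BODY_Y[1]
    z_me = z_body_top - (me_y - go_mid_y) * np.tan(np.radians(spec.ml_nl_deg))
    body = _box(*BODY_X, *BODY_Y, z_me, z_body_top)
    body_volume = ((BODY_X[1] - BODY_X[0]) * (BODY_Y[1] - BODY_Y[0])
                   * (z_body_top - z_me))

    parts = [body, condyle_l, coronoid_l, ramus_l,
             _mirror(condyle_l), _mirror(coronoid_l), _mirror(ramus_l)]
    mesh = trimesh.util.concatenate(parts)
    if not mesh.is_watertight:
        raise PhantomError("assembled phantom is not watertight "
                           "(generation bug)")

    mand_volume = body_volume + 2 * (ramus_volume + cor_volume + c_volume)

    landmarks = {
        "porion_left": [55.0, 0.0, 0.0],
        "porion_right": [-55.0, 0.0, 0.0],
        "orbitale": [25.0, 65.0, 0.0],
        "nasion": [0.0, 72.0, 8.0],
        "Me": [float(spec.menton_offset), me_y, float(z_me)],
        "A": [0.0, 58.0, Z_OCCLUSAL + 7.0],
        "B": [0.0, 58.0 - float(spec.wits_mm), Z_OCCLUSAL - 7.0],
        "ANS": [0.0, 65.0, Z_NASAL_LINE],
        "PNS": [0.0, 20.0, Z_NASAL_LINE],
        "Go_left": [42.0, go_mid_y, float(z_body_top)],
        "Go_right": [-42.0, go_mid_y, float(z_body_top)],
        "occlusal_1": [-20.0, 30.0, Z_OCCLUSAL],
        "occlusal_2": [20.0, 30.0, Z_OCCLUSAL],
        "occlusal_3": [0.0, 55.0, Z_OCCLUSAL],
        "notch_left": [42.0, 18.5, Z_NOTCH],
        "notch_right": [-42.0, 18.5, Z_NOTCH],
    }

    incl_ap, incl_ml = _achieved_angles(R, D2)
    side_metrics = CondylarMetrics(
        c_depth=float(np.linalg.norm(p_ant - p_post)),
        c_width=float(np.linalg.norm(p_lat - p_med)),
        c_height=float(p_cran[2] - Z_NOTCH),
        c_incl_ap=incl_ap, c_incl_ml=incl_ml,
        c_volume=float(c_volume))
    gt = GroundTruth(
        left=side_metrics, right=side_metrics,
        mand_volume=float(mand_volume),
        ratio_per_side=100.0 * c_volume / mand_volume,
        ratio_summed=100.0 * 2 * c_volume / mand_volume,
        me_msp=float(spec.menton_offset),
        wits=float(spec.wits_mm),
        ml_nl=float(spec.ml_nl_deg),
        notch_z=Z_NOTCH)
    return mesh, landmarks, gt
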