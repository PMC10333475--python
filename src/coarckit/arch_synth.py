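"""Parametric aortic-arch phantoms.

Generates analytic centerline + radius representations of gothic (triangular),
crenel (rectangular) and romanesque (round) aortic arches in the
oblique-sagittal measurement plane, with named anatomical landmarks, optional
coarctation (a cosine-tapered stenosis of the isthmus), branch stubs for the
brachiocephalic trunk / LCCA / LSCA, and a voxelizer producing binary masks.

Cohort sampling draws per-group arch parameters from (mean, SEM, n) summary
triplets, the form in which published group tables report them.

Conventions: world coordinates are millimetres; the arch plane is x
(horizontal) x y (vertical) embedded at z = 0; the arch opens downward
(apex at the top). The "T-line" joins the end of the ascending aorta to the
midpoint of the descending aorta; arch height A is the apex's perpendicular
distance to it and width T the distance between its endpoints.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from ._geometry import Arc, Line, PiecewiseCurve, fillet_corner, line_angle_deg, ray_angle_deg

ARCH_TYPES = ("gothic", "crenel", "romanesque")

#: measurement stations, in anatomical (arc-length) order
LEVELS = ("AOA", "D1", "D2", "D3", "D4", "D5")

#: half-width (mm) of the constant-radius plateau kept around each level
#: station so that windowed maximum-diameter measurement recovers the
#: generated value exactly; must exceed the measurement window (2.5 mm)
PLATEAU_HALF_WIDTH = 3.0

#: cohort-scale defaults for quantities the group tables do not constrain
DEFAULT_WIDTH_MEAN = 36.0   # mm, arch width T of an infant aorta
DEFAULT_WIDTH_SD = 4.0
DEFAULT_AOA_MEAN = 12.0     # mm, ascending-aorta caliber
DEFAULT_AOA_SD = 1.5


class InfeasibleGeometryError(ValueError):
    """Requested arch parameters are jointly unsatisfiable."""


@dataclass
class ArchParams:
    """Full parametric description of one synthetic arch."""

    arch_type: str = "romanesque"
    height_A: float = 21.0          # mm
    width_T: float = 36.0           # mm
    aao_dao_angle: float = 32.0     # degrees, acute
    tao_dao_angle: float = 110.0    # degrees
    level_diameters: dict = field(default_factory=lambda: {
        "AOA": 12.0, "D1": 10.2, "D2": 9.0, "D3": 7.0, "D4": 8.5, "D5": 7.8})
    stenosis_severity: float = 0.0      # fraction of local radius removed
    stenosis_location: float = 0.5      # arc-length fraction along the isthmus
    stenosis_length: float = 8.0        # mm, full cosine-taper extent
    branch_diameters: dict = field(default_factory=lambda: {
        "brachiocephalic": 6.0, "LCCA": 4.5, "LSCA": 4.5})
    segment_lengths: dict = field(default_factory=dict)  # 'ascending', 'descending'
    seed: int = 0

    def __post_init__(self):
        if self.arch_type not in ARCH_TYPES:
            raise ValueError(f"arch_type must be one of {ARCH_TYPES}")
        if self.height_A <= 0 or self.width_T <= 0:
            raise ValueError("height_A and width_T must be positive")
        if not (0.0 < self.aao_dao_angle < 90.0):
            raise ValueError("aao_dao_angle must lie in (0, 90) degrees")
        if not (90.0 < self.tao_dao_angle < 180.0):
            raise ValueError("tao_dao_angle must lie in (90, 180) degrees")
        if not (0.0 <= self.stenosis_severity < 1.0):
            raise ValueError("stenosis_severity must lie in [0, 1)")
        if not (0.0 <= self.stenosis_location <= 1.0):
            raise ValueError("stenosis_location must lie in [0, 1]")
        for name, d in {**self.level_diameters, **self.branch_diameters}.items():
            if d <= 0:
                raise ValueError(f"diameter {name} must be positive")
        defaults = {"ascending": 0.7 * self.width_T,
                    "descending": float(np.clip(0.8 * self.height_A, 17.0, 40.0))}
        self.segment_lengths = {**defaults, **self.segment_lengths}

    @property
    def at_ratio(self) -> float:
        return self.height_A / self.width_T


@dataclass
class Landmark:
    s: float               # arc length along the centerline, mm
    point: np.ndarray      # world xyz, mm


@dataclass
class Centerline:
    """Ordered centerline with arc-length parameter and radius profile."""

    s: np.ndarray          # (N,) strictly increasing, mm
    points: np.ndarray     # (N, 3) world, mm
    radii: np.ndarray      # (N,) mm

    @property
    def length(self) -> float:
        return float(self.s[-1] - self.s[0])

    def point_at(self, s: float) -> np.ndarray:
        return np.array([np.interp(s, self.s, self.points[:, i]) for i in range(3)])

    def radius_at(self, s) -> np.ndarray:
        return np.interp(s, self.s, self.radii)


@dataclass
class AnalyticArch:
    centerline: Centerline
    landmarks: dict            # name -> Landmark
    branch_stubs: list         # (name, points (M,3), radius)
    params: ArchParams

    @property
    def s(self):
        return self.centerline.s

    @property
    def points(self):
        return self.centerline.points

    @property
    def radii(self):
        return self.centerline.radii


@dataclass
class VoxelMask:
    """Binary vascular mask on a regular grid with world metadata."""

    grid: np.ndarray           # (nx, ny, nz) uint8, foreground = 1
    spacing: np.ndarray        # (3,) mm per axis
    origin: np.ndarray         # (3,) world coordinate of voxel (0,0,0) center
    landmarks: dict | None = None   # name -> world xyz

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class GroupSummary:
    """Per-group (mean, SEM) summaries in the layout of a clinical table."""

    label: str
    n: int
    variables: dict            # name -> (mean, sem)
    proportions: dict = field(default_factory=dict)   # name -> fraction

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("group size must be positive")
        for name, (mean, sem) in self.variables.items():
            if sem < 0:
                raise ValueError(f"SEM of {name} must be non-negative")

    def sd(self, name: str) -> float:
        return self.variables[name][1] * np.sqrt(self.n)


# ---------------------------------------------------------------------------
# arch construction
# ---------------------------------------------------------------------------

def _gothic_pieces(A, T, h, apex_radius):
    """Two near-straight limbs joined by a small apex arc of exact height A."""
    E = np.array([0.0, 0.0])
    Ds = np.array([T, h])
    xc = T / 2.0

    def top_of(Hc):
        t0, arc, t1 = fillet_corner(E, np.array([xc, Hc]), Ds, apex_radius)
        return arc.top_y()

    lo = max(A, h) + 1e-9
    hi = None
    for Hc in np.linspace(lo, lo + 6 * apex_radius + 0.5 * A, 80):
        try:
            if top_of(Hc) > A:
                hi = Hc
                break
        except ValueError:
            break
        lo = Hc
    if hi is None:
        raise InfeasibleGeometryError(
            "gothic apex unreachable: height_A is too large relative to "
            "width_T / descending length for the apex fillet radius")
    Hc = brentq(lambda x: top_of(x) - A, lo, hi, xtol=1e-12)
    corner = np.array([xc, Hc])
    t0, arc, t1 = fillet_corner(E, corner, Ds, apex_radius)
    pieces = [Line(E, t0), arc, Line(t1, Ds)]
    # exact apex: topmost point of the fillet circle
    k = np.ceil((min(arc.a0, arc.a1) - np.pi / 2) / (2 * np.pi))
    a_top = np.pi / 2 + 2 * np.pi * k
    s_apex = pieces[0].length + arc.s_of_angle(a_top)
    return pieces, s_apex


def _crenel_pieces(A, T, h):
    """Two vertical limbs joined by a flat top with rounded corners."""
    rc = min(0.25 * T, 0.45 * (A - h), 0.45 * A)
    if rc <= 0.5 or T - 2 * rc <= 1.0:
        raise InfeasibleGeometryError(
            "crenel corners unbuildable: height_A too small relative to the "
            "descending length / width_T")
    pieces = [
        Line(np.array([0.0, 0.0]), np.array([0.0, A - rc])),
        Arc(np.array([rc, A - rc]), rc, np.pi, np.pi / 2),
        Line(np.array([rc, A]), np.array([T - rc, A])),
        Arc(np.array([T - rc, A - rc]), rc, np.pi / 2, 0.0),
        Line(np.array([T, A - rc]), np.array([T, h])),
    ]
    s_apex = pieces[0].length + pieces[1].length + pieces[2].length / 2.0
    return pieces, s_apex


def _romanesque_pieces(A, T, h):
    """A single circular arc of exact apex height A through both shoulders."""
    if h == 0.0:
        cx = T / 2.0
    else:
        a, b, c = h, -2 * A * T, A * T**2 + A * h**2 - h * A**2
        disc = b * b - 4 * a * c
        if disc < 0:
            raise InfeasibleGeometryError(
                "romanesque arc unbuildable for this height_A / width_T / "
                "descending length combination")
        cx = (-b - np.sqrt(disc)) / (2 * a)
    cy = (A**2 - cx**2) / (2 * A)
    R = A - cy
    if R <= 0 or not (0 < cx < T):
        raise InfeasibleGeometryError(
            "romanesque arc unbuildable: height_A incompatible with width_T")
    a0 = float(np.arctan2(0.0 - cy, 0.0 - cx)) % (2 * np.pi)
    a1 = float(np.arctan2(h - cy, T - cx))
    if not (a0 > np.pi / 2 > a1):
        raise InfeasibleGeometryError(
            "romanesque apex does not lie between the shoulders "
            "(height_A vs width_T vs descending length)")
    arc = Arc(np.array([cx, cy]), R, a0, a1)
    return [arc], arc.s_of_angle(np.pi / 2)


def build_arch(params: ArchParams) -> AnalyticArch:
    """Construct the analytic centerline + radius phantom for ``params``.

    Height, width, both chord angles, level diameters and the stenosis throat
    are satisfied by construction (root solves run to ~1e-12 mm). Raises
    :class:`InfeasibleGeometryError` when the requested quantities are
    jointly unsatisfiable, naming the conflicting parameters.
    """
    A, T = params.height_A, params.width_T
    La = params.segment_lengths["ascending"]
    Ld = params.segment_lengths["descending"]
    h = Ld / 2.0
    if h >= 0.85 * A:
        raise InfeasibleGeometryError(
            "descending segment length too large for height_A: the "
            "descending midpoint would rise above the arch")

    if params.arch_type == "gothic":
        apex_radius = 0.2 * min(T, A)
        arch_pieces, s_apex_local = _gothic_pieces(A, T, h, apex_radius)
    elif params.arch_type == "crenel":
        arch_pieces, s_apex_local = _crenel_pieces(A, T, h)
    else:
        arch_pieces, s_apex_local = _romanesque_pieces(A, T, h)

    P0 = np.array([0.0, -La])
    E = np.array([0.0, 0.0])
    Ds = np.array([T, h])
    Pend = np.array([T, h - Ld])
    M = np.array([T, 0.0])
    curve = PiecewiseCurve([Line(P0, E)] + arch_pieces + [Line(Ds, Pend)])

    s_E = La
    s_apex = La + s_apex_local
    s_Ds = curve.length - Ld
    s_M = s_Ds + h
    s_end = curve.length

    # --- place branch landmarks so the requested chord angles hold ---------
    # (the stenosis taper may spill past the isthmus ends, so only a short
    # stretch is reserved between the LSCA and the descending aorta)
    min_isthmus = 6.0

    def chord_angles(sB, sS):
        B = curve.point(sB)[0]
        S = curve.point(sS)[0]
        aao = line_angle_deg(B - P0, Pend - S)
        tao = ray_angle_deg(B - S, Pend - S)
        return aao, tao

    def solve_sB(sS):
        S = curve.point(sS)[0]

        def g(sB):
            B = curve.point(sB)[0]
            return line_angle_deg(B - P0, Pend - S) - params.aao_dao_angle

        lo, hi = s_E + 0.5, s_apex - 0.5
        if hi <= lo or g(lo) > 0 or g(hi) < 0:
            return None
        return brentq(g, lo, hi, xtol=1e-11)

    def tao_residual(sS):
        sB = solve_sB(sS)
        if sB is None:
            return None
        return chord_angles(sB, sS)[1] - params.tao_dao_angle

    grid = np.linspace(s_apex + 0.5, s_Ds - min_isthmus, 48)
    if grid[-1] <= grid[0]:
        raise InfeasibleGeometryError(
            "no room for an isthmus: stenosis_length too large for the arch "
            "arc (height_A, width_T)")
    vals = [tao_residual(s) for s in grid]
    s_S = None
    for (sa, fa), (sb, fb) in zip(zip(grid, vals), zip(grid[1:], vals[1:])):
        if fa is None or fb is None:
            continue
        if fa == 0.0:
            s_S = sa
            break
        if fa * fb < 0:
            s_S = brentq(lambda s: tao_residual(s), sa, sb, xtol=1e-11)
            break
    if s_S is None:
        raise InfeasibleGeometryError(
            "aao_dao_angle and tao_dao_angle jointly unsatisfiable on this "
            "arch (height_A, width_T, aao_dao_angle, tao_dao_angle)")
    s_B = solve_sB(s_S)
    s_LCCA = 0.5 * (s_B + s_S)

    # --- level stations and radius profile ---------------------------------
    stations = {
        "AOA": La / 2.0,
        "D1": 0.5 * (s_B + s_LCCA),
        "D2": 0.5 * (s_LCCA + s_S),
        "D3": 0.5 * (s_S + s_Ds),
        "D4": s_M,
        # the diaphragm crossing sits just inside the modeled domain so the
        # windowed diameter search does not run off the end
        "D5": s_end - 3.0,
    }
    s_sta = np.array([stations[k] for k in LEVELS])
    r_sta = np.array([params.level_diameters[k] / 2.0 for k in LEVELS])
    gaps = np.diff(s_sta)
    if np.any(gaps < 2 * PLATEAU_HALF_WIDTH - 0.8):
        raise InfeasibleGeometryError(
            "level stations too crowded for the measurement plateaus "
            "(height_A, width_T or segment_lengths too small)")
    plateau = min(PLATEAU_HALF_WIDTH, float(gaps.min()) / 2.0 - 0.1)

    s_sten = s_S + params.stenosis_location * (s_Ds - s_S)

    def radius_profile(s):
        s = np.asarray(s, float)
        r = np.empty_like(s)
        r[s <= s_sta[0]] = r_sta[0]
        r[s >= s_sta[-1]] = r_sta[-1]
        for i in range(len(s_sta) - 1):
            m = (s >= s_sta[i]) & (s <= s_sta[i + 1])
            if not m.any():
                continue
            lo, hi = s_sta[i] + plateau, s_sta[i + 1] - plateau
            t = np.clip((s[m] - lo) / (hi - lo), 0.0, 1.0)
            w = 0.5 * (1.0 - np.cos(np.pi * t))       # smooth 0 -> 1
            r[m] = r_sta[i] * (1 - w) + r_sta[i + 1] * w
        if params.stenosis_severity > 0:
            half = params.stenosis_length / 2.0
            m = np.abs(s - s_sten) < half
            taper = 0.5 * (1 + np.cos(np.pi * (s[m] - s_sten) / half))
            r[m] = r[m] * (1 - params.stenosis_severity * taper)
        return r

    # --- sample the centerline, keeping exact special points ---------------
    special = np.array(sorted({*curve.knots(), *s_sta, s_B, s_S, s_LCCA,
                               s_apex, s_sten, s_E, s_Ds, s_M}))
    s = np.union1d(np.arange(0.0, curve.length, 0.25), special)
    s = np.union1d(s, [curve.length])
    pts2d = curve.point(s)
    points = np.column_stack([pts2d, np.zeros(len(s))])
    radii = radius_profile(s)

    def lm(sv):
        p = curve.point(sv)[0]
        return Landmark(float(sv), np.array([p[0], p[1], 0.0]))

    landmarks = {
        "ascending_start": lm(0.0),
        "ascending_end": lm(s_E),
        "brachiocephalic_anterior": lm(s_B),
        "left_common_carotid": lm(s_LCCA),
        "lscA_posterior": lm(s_S),
        "arch_apex": lm(s_apex),
        "descending_start": lm(s_Ds),
        "descending_mid": lm(s_M),
        "descending_end": lm(s_end),
        "stenosis_center": lm(s_sten),
        **{k: lm(stations[k]) for k in LEVELS},
    }

    # --- branch stubs, pointing away from the arch interior -----------------
    ref = np.array([T / 2.0, 0.0, 0.0])
    stubs = []
    for name, sv in (("brachiocephalic", s_B), ("LCCA", s_LCCA), ("LSCA", s_S)):
        p = landmarks_point = landmarks[
            {"brachiocephalic": "brachiocephalic_anterior",
             "LCCA": "left_common_carotid",
             "LSCA": "lscA_posterior"}[name]].point
        d = p - ref
        d = d / np.linalg.norm(d)
        stub_pts = p + np.outer(np.linspace(0, 8.0, 17), d)
        stubs.append((name, stub_pts, params.branch_diameters[name] / 2.0))

    cl = Centerline(s=s, points=points, radii=radii)
    return AnalyticArch(centerline=cl, landmarks=landmarks,
                        branch_stubs=stubs, params=params)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxelize(arch: AnalyticArch, spacing: float | tuple = 0.4,
             include_branches: bool = True, margin: float = 2.0) -> VoxelMask:
    """Rasterize the tube around the centerline onto a regular binary grid.

    A voxel is foreground when its center lies inside the tube of radius
    ``radius_profile(s)`` around the nearest centerline point. ``spacing``
    may be a scalar or per-axis triple (mm) and must satisfy the sampling
    guard ``spacing <= min radius / 2``.
    """
    spacing = np.broadcast_to(np.asarray(spacing, float), 3).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    rmin = float(arch.radii.min())
    if spacing.max() > rmin / 2.0:
        raise ValueError(
            f"spacing {spacing.max():g} mm too coarse for the thinnest lumen "
            f"(radius {rmin:g} mm); use spacing <= {rmin / 2.0:g} mm")

    # dense samples per tubular structure; the mask is the union of tubes,
    # so each structure is tested on its own (the nearest sample overall may
    # belong to a thinner branch passing through the main lumen)
    cl = arch.centerline
    ds = float(spacing.min()) / 2.0
    s_dense = np.union1d(np.arange(cl.s[0], cl.s[-1], ds), cl.s)
    pts = np.column_stack([np.interp(s_dense, cl.s, cl.points[:, i]) for i in range(3)])
    structures = [(pts, np.interp(s_dense, cl.s, cl.radii))]
    if include_branches:
        for _, stub_pts, r in arch.branch_stubs:
            seglen = np.linalg.norm(stub_pts[-1] - stub_pts[0])
            t = np.linspace(0, 1, max(int(seglen / ds), 2))
            p = stub_pts[0] + np.outer(t, stub_pts[-1] - stub_pts[0])
            structures.append((p, np.full(len(p), float(r))))

    all_pts = np.vstack([p for p, _ in structures])
    rmax = max(r.max() for _, r in structures)
    lo = all_pts.min(axis=0) - rmax - margin
    hi = all_pts.max(axis=0) + rmax + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    trees = [(cKDTree(p), r) for p, r in structures]

    grid = np.zeros(shape, dtype=np.uint8)
    xs = lo[0] + np.arange(shape[0]) * spacing[0]
    ys = lo[1] + np.arange(shape[1]) * spacing[1]
    zs = lo[2] + np.arange(shape[2]) * spacing[2]
    # chunk along x to bound memory
    step = max(1, int(2e6 // (shape[1] * shape[2])))
    for i0 in range(0, shape[0], step):
        X, Y, Z = np.meshgrid(xs[i0:i0 + step], ys, zs, indexing="ij")
        centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        inside = np.zeros(len(centers), dtype=bool)
        for tree, rad in trees:
            dist, idx = tree.query(centers[~inside], k=1, workers=-1)
            hit = dist <= rad[idx]
            where = np.flatnonzero(~inside)
            inside[where[hit]] = True
        grid[i0:i0 + step] = inside.reshape(X.shape).astype(np.uint8)

    landmarks = {k: v.point.copy() for k, v in arch.landmarks.items()}
    return VoxelMask(grid=grid, spacing=spacing, origin=lo, landmarks=landmarks)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

#: variables a GroupSummary must provide to drive arch synthesis
MORPHO_VARS = ("A_T", "AAO_DAO", "TAO_DAO",
               "D1_AOA", "D2_AOA", "D3_AOA", "D4_AOA", "D5_AOA")

_CLAMPS = {
    "A_T": (0.33, 1.05),
    "AAO_DAO": (8.0, 60.0),
    "TAO_DAO": (95.0, 160.0),
    "D1_AOA": (0.15, 1.3),
    "D2_AOA": (0.15, 1.3),
    "D3_AOA": (0.12, 1.3),
    "D4_AOA": (0.15, 1.3),
    "D5_AOA": (0.15, 1.3),
}


def _draw(rng, mean, sd, lo=None, hi=None, tries=100):
    """Normal draw truncated to [lo, hi] by redraw (falls back to clipping)."""
    if sd == 0:
        return float(mean)
    for _ in range(tries):
        x = rng.normal(mean, sd)
        if (lo is None or x >= lo) and (hi is None or x <= hi):
            return float(x)
    return float(np.clip(x, lo, hi))


def _params_from_draws(label, d, aoa, width, seed):
    diam = {"AOA": aoa, **{f"D{i}": d[f"D{i}_AOA"] * aoa for i in range(1, 6)}}
    scale = aoa / DEFAULT_AOA_MEAN
    return ArchParams(
        arch_type=label,
        height_A=d["A_T"] * width,
        width_T=width,
        aao_dao_angle=d["AAO_DAO"],
        tao_dao_angle=d["TAO_DAO"],
        level_diameters=diam,
        branch_diameters={"brachiocephalic": 6.0 * scale,
                          "LCCA": 4.5 * scale, "LSCA": 4.5 * scale},
        seed=seed,
    )


def sample_cohort(summaries, seed: int, ensure_buildable: bool = True):
    """Draw a cohort of :class:`ArchParams`, one group per summary.

    Each variable is drawn as Normal(mean, sd = sem * sqrt(n)), truncated to
    positivity/feasibility. With ``ensure_buildable`` every returned
    parameter set is verified against :func:`build_arch` (infeasible draws
    are redrawn; as a last resort the chord angles fall back to the group
    means).
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for g in summaries:
        for j in range(g.n):
            case_seed = int(rng.integers(0, 2**31 - 1))
            for attempt in range(50):
                d = {}
                for name in MORPHO_VARS:
                    mean, sem = g.variables[name]
                    lo, hi = _CLAMPS[name]
                    d[name] = _draw(rng, mean, g.sd(name), lo, hi)
                aoa = _draw(rng, DEFAULT_AOA_MEAN, DEFAULT_AOA_SD, 8.0, 16.0)
                width = _draw(rng, DEFAULT_WIDTH_MEAN, DEFAULT_WIDTH_SD, 26.0, 46.0)
                p = _params_from_draws(g.label, d, aoa, width, case_seed)
                if not ensure_buildable:
                    break
                try:
                    build_arch(p)
                    break
                except InfeasibleGeometryError:
                    continue
            else:
                d["AAO_DAO"] = g.variables["AAO_DAO"][0]
                d["TAO_DAO"] = g.variables["TAO_DAO"][0]
                p = _params_from_draws(g.label, d, aoa, width, case_seed)
                build_arch(p)
            cohort.append(p)
    return cohort


#: clinical variables carried alongside the morphometric ones
CLINICAL_VARS = ("age_months", "weight_kg", "pspg_mmhg")


def sample_cohort_table(summaries, seed: int, ensure_buildable: bool = True):
    """Sample a cohort and return (records DataFrame, list of ArchParams).

    The frame carries group labels, clinical draws (normal, truncated to
    positive) and Bernoulli categorical draws where the summary specifies
    proportions, ready for the published-table style rebuild.
    """
    import pandas as pd

    params = sample_cohort(summaries, seed, ensure_buildable=ensure_buildable)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31 - 1))
    rows = []
    i = 0
    for g in summaries:
        for _ in range(g.n):
            p = params[i]
            i += 1
            row = {"group": g.label, "at_ratio_true": p.at_ratio,
                   "aoa_mm": p.level_diameters["AOA"]}
            for name in CLINICAL_VARS:
                if name in g.variables:
                    mean, sem = g.variables[name]
                    row[name] = _draw(rng, mean, g.sd(name), lo=0.05)
            for name, frac in g.proportions.items():
                row[name] = int(rng.random() < frac)
            rows.append(row)
    return pd.DataFrame(rows), params


def default_network_case() -> ArchParams:
    """The gothic coarctation phantom behind the hemodynamic reference run.

    Level diameters are normal pediatric calibers (AOA 12 mm); the isthmus
    narrowing is introduced by the stenosis element, whose throat area is the
    free calibration parameter.
    """
    return ArchParams(
        arch_type="gothic",
        height_A=0.70148 * 36.0,
        width_T=36.0,
        aao_dao_angle=26.74,
        tao_dao_angle=109.81,
        stenosis_severity=0.0,
        stenosis_location=0.5,
    )
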