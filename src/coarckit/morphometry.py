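"""Arch morphometry: the oblique-sagittal measurement constructions.

Implements, on centerline + radius geometry (analytic phantoms or voxel
masks with a landmark file):

* level diameters AOA, D1..D5 (windowed maximum inscribed diameter),
* arch height A, width T and the A/T ratio,
* the AAO-DAO and TAO-DAO chord angles,
* height-to-width arch classification (gothic / romanesque / crenel), and
* hypoplastic-arch and coarctation screening criteria on the Di/AOA ratios.

"Horizontal" and "vertical" are defined relative to the T-line (the chord
from the end of the ascending aorta to the midpoint of the descending
aorta), which makes every output invariant to rigid motions and to scaling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import line_angle_deg, ray_angle_deg
from .arch_synth import LEVELS, AnalyticArch, Centerline, Landmark, VoxelMask

#: A/T breakpoints of the height-to-width classification
GOTHIC_AT = 0.8
CRENEL_AT = 0.6

#: Di/AOA thresholds of the hypoplastic-aortic-arch criteria
HAA_THRESHOLDS = {"proximal": 0.60, "distal": 0.50, "isthmus": 0.40}

#: stenosis-to-reference diameter threshold of the coarctation criterion
COA_FRACTION = 0.50

#: half-width (mm) of the arc-length search window for "maximum inner
#: diameter" at a level station
LEVEL_WINDOW = 2.5

_REQUIRED_LANDMARKS = ("ascending_end", "brachiocephalic_anterior",
                       "lscA_posterior", "descending_mid")


@dataclass
class ArchMeasurements:
    """One patient-style measurement record."""

    diameters: dict                    # level -> mm
    ratios: dict                       # 'D1_AOA'.. -> dimensionless
    height_A: float
    width_T: float
    at_ratio: float
    aao_dao_angle: float
    tao_dao_angle: float
    arch_class: str = ""
    haa_flags: dict = field(default_factory=dict)
    coa_flag: bool = False

    def as_row(self) -> dict:
        row = {k: self.diameters[k] for k in self.diameters}
        row.update(self.ratios)
        row.update(A=self.height_A, T=self.width_T, A_T=self.at_ratio,
                   AAO_DAO=self.aao_dao_angle, TAO_DAO=self.tao_dao_angle,
                   arch_class=self.arch_class, coa=self.coa_flag)
        row.update({f"haa_{k}": v for k, v in self.haa_flags.items()})
        return row


def _as_landmark_map(centerline: Centerline, landmarks) -> dict:
    """Normalize landmarks to name -> Landmark(s, point) on this centerline.

    Accepts Landmark values (arc position kept) or bare world points, which
    are projected to the nearest centerline sample.
    """
    out = {}
    for name, v in landmarks.items():
        if isinstance(v, Landmark):
            out[name] = v
        else:
            p = np.asarray(v, float)
            i = int(np.argmin(np.linalg.norm(centerline.points - p, axis=1)))
            out[name] = Landmark(float(centerline.s[i]), p)
    missing = [n for n in _REQUIRED_LANDMARKS if n not in out]
    if missing:
        raise ValueError(f"missing required landmarks: {missing}")
    return out


def _resolve(obj, landmarks=None):
    """Return (centerline, landmark map) from an arch, mask or centerline."""
    if isinstance(obj, AnalyticArch):
        return obj.centerline, _as_landmark_map(obj.centerline, landmarks or obj.landmarks)
    if isinstance(obj, VoxelMask):
        cl = extract_centerline(obj)
        return cl, _as_landmark_map(cl, landmarks or obj.landmarks or {})
    if isinstance(obj, Centerline):
        if landmarks is None:
            raise ValueError("landmarks are required with a bare centerline")
        return obj, _as_landmark_map(obj, landmarks)
    raise TypeError(f"cannot measure a {type(obj).__name__}")


# ---------------------------------------------------------------------------
# centerline extraction from voxel masks
# ---------------------------------------------------------------------------

def extract_centerline(mask: VoxelMask, resample_mm: float = 0.25,
                       smooth_window: int = 3) -> Centerline:
    """Skeleton-based centerline with cross-sectional inscribed radii.

    The binary mask must be a single connected tubular component. The
    skeleton graph's weighted-longest path is taken as the vessel axis
    (which prunes short branch stubs), ordered from the ascending end when
    the mask carries landmarks, lightly smoothed with an endpoint-preserving
    moving average, extended along its end tangents to the mask caps (3-D
    thinning erodes blunt tube ends), and resampled to ``resample_mm``.
    Radii are maximal inscribed radii in the cross-section perpendicular to
    the local tangent, estimated from boundary voxels.
    """
    import networkx as nx
    from scipy import ndimage
    from scipy.spatial import cKDTree
    from skimage.measure import label
    from skimage.morphology import skeletonize

    grid = mask.grid.astype(bool)
    lab = label(grid, connectivity=1)
    ncomp = lab.max()
    if ncomp != 1:
        raise ValueError(f"mask must be a single connected component, found {ncomp}")

    skel = skeletonize(grid)
    coords = np.argwhere(skel)
    if len(coords) < 3:
        raise ValueError("skeleton too short; is the mask a tube?")
    index = {tuple(c): i for i, c in enumerate(coords)}
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) > (0, 0, 0)]
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    sp = np.asarray(mask.spacing, float)
    for i, c in enumerate(coords):
        for off in offsets:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                g.add_edge(i, j, weight=float(np.linalg.norm(off * sp)))

    # small junction loops are ordinary skeleton artifacts; only a loop of
    # anatomical size means the mask is not a tree
    cycles = nx.cycle_basis(g)
    big = [c for c in cycles if len(c) * float(np.max(sp)) > 20.0]
    if big:
        where = coords[big[0]].mean(axis=0) * sp + mask.origin
        raise ValueError(f"skeleton contains a loop near world {np.round(where, 1)}; "
                         "mask is not a simple tube")

    # double-sweep weighted eccentricity: farthest pair = main vessel axis
    def farthest(src):
        d = nx.single_source_dijkstra_path_length(g, src)
        return max(d, key=d.get)

    a = farthest(next(iter(g.nodes)))
    b = farthest(a)
    path = nx.dijkstra_path(g, a, b)
    pts = coords[path] * sp + mask.origin

    if mask.landmarks and "ascending_end" in mask.landmarks:
        e = np.asarray(mask.landmarks["ascending_end"], float)
        if np.linalg.norm(pts[-1] - e) < np.linalg.norm(pts[0] - e):
            pts = pts[::-1]

    # endpoint-preserving smoothing: shrink the window near the ends
    half = smooth_window // 2
    sm = np.empty_like(pts)
    for i in range(len(pts)):
        w = min(half, i, len(pts) - 1 - i)
        sm[i] = pts[i - w:i + w + 1].mean(axis=0)

    edt = ndimage.distance_transform_edt(grid, sampling=sp)

    def edt_at(p):
        idx = np.round((p - mask.origin) / sp).astype(int)
        if np.any(idx < 0) or np.any(idx >= grid.shape):
            return 0.0
        return float(edt[tuple(idx)])

    def extend(points, flip):
        # walk along the end tangent; stop where the distance map starts its
        # end-cap falloff (the vessel truly ends there, not where thinning
        # stopped)
        if flip:
            points = points[::-1]
        tang = points[-1] - points[-min(len(points) - 1, 8)]
        tang = tang / np.linalg.norm(tang)
        step = float(sp.min())
        extra, edts = [], []
        p = points[-1]
        for _ in range(int(40.0 / step)):
            p = p + tang * step
            if edt_at(p) <= 0.0:
                break
            extra.append(p.copy())
            edts.append(edt_at(p))
        if extra:
            plateau = max(edts)
            keep = [i for i, e in enumerate(edts) if e >= plateau - 0.9 * float(sp.max())]
            if keep:
                points = np.vstack([points, extra[:keep[-1] + 1]])
        return points[::-1] if flip else points

    sm = extend(sm, flip=False)
    sm = extend(sm, flip=True)

    seg = np.linalg.norm(np.diff(sm, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_new = np.union1d(np.arange(0.0, s[-1], resample_mm), [s[-1]])
    pts_new = np.column_stack([np.interp(s_new, s, sm[:, i]) for i in range(3)])

    def tangents_of(pts_arr, s_arr):
        t = np.gradient(pts_arr, s_arr, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    # recentre each point to the distance-map maximum within its
    # perpendicular plane: thinning drifts off-axis near branch junctions
    tangents = tangents_of(pts_new, s_new)
    off = np.arange(-2.0, 2.0 + 1e-9, 0.25)
    for i in range(len(pts_new)):
        t = tangents[i]
        u = np.cross(t, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(t, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        cand = (pts_new[i] + off[:, None, None] * u + off[None, :, None] * v).reshape(-1, 3)
        vals = np.array([edt_at(p) for p in cand])
        # the distance map is nearly flat around the axis; the centroid of
        # near-maximal candidates localizes the axis better than the argmax
        near = vals >= vals.max() - 0.45 * float(sp.min())
        pts_new[i] = cand[near].mean(axis=0)

    seg = np.linalg.norm(np.diff(pts_new, axis=0), axis=1)
    s_new = np.concatenate([[0.0], np.cumsum(seg)])
    tangents = tangents_of(pts_new, s_new)

    # cross-sectional maximal inscribed radius from boundary voxels
    shell = grid & ~ndimage.binary_erosion(grid)
    bpts = np.argwhere(shell) * sp + mask.origin
    btree = cKDTree(bpts)
    rad_new = np.empty(len(pts_new))
    slab = 0.75 * float(sp.max())
    dists, idxs = btree.query(pts_new, k=min(80, len(bpts)), workers=-1)
    halfvox = 0.5 * float(sp.mean())
    for i in range(len(pts_new)):
        rel = bpts[idxs[i]] - pts_new[i]
        axial = np.abs(rel @ tangents[i])
        ok = axial < slab
        d = dists[i][ok].min() if ok.any() else dists[i].min()
        rad_new[i] = d + halfvox  # boundary-shell centers sit half a voxel in
    return Centerline(s=s_new, points=pts_new, radii=rad_new)


# ---------------------------------------------------------------------------
# measurement constructions
# ---------------------------------------------------------------------------

def measure_diameters(obj, landmarks=None, window: float = LEVEL_WINDOW) -> dict:
    """Level diameters: max inscribed diameter within +-window of each station."""
    import warnings

    cl, lms = _resolve(obj, landmarks)
    out = {}
    for level in LEVELS:
        if level not in lms:
            raise ValueError(f"missing level station landmark {level}")
        sk = lms[level].s
        if sk - window < cl.s[0] or sk + window > cl.s[-1]:
            warnings.warn(f"measurement window at {level} clipped to the centerline")
        m = np.abs(cl.s - sk) <= window
        out[level] = float(2.0 * cl.radii[m].max())
    return out


def compute_arch_geometry(obj, landmarks=None) -> dict:
    """Arch height A, width T, A/T and the AAO-DAO / TAO-DAO chord angles.

    T is the distance from the ascending-aorta endpoint to the descending
    midpoint (the T-line); A the perpendicular distance from the centerline's
    apex — on the arch side of the T-line — to that line. The AAO line runs
    from the start of the ascending aorta to the brachiocephalic landmark;
    the DAO line from the descending end to the LSCA landmark; the TAO chord
    joins the two branch landmarks. AAO-DAO is the acute intersection angle;
    TAO-DAO the angle at the LSCA landmark between the TAO and DAO chords.
    """
    cl, lms = _resolve(obj, landmarks)
    pts = cl.points
    E = lms["ascending_end"].point
    M = lms["descending_mid"].point
    B = lms["brachiocephalic_anterior"].point
    S = lms["lscA_posterior"].point
    if np.linalg.norm(M - E) < 1e-12:
        raise ValueError("degenerate T-line: ascending_end and descending_mid coincide")

    # work in the best-fit plane when the centerline is not already planar
    centered = pts - pts.mean(axis=0)
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    rms_out = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    if rms_out > 1.0:
        proj = lambda p: (p - pts.mean(axis=0)) - np.outer((p - pts.mean(axis=0)) @ normal, normal)
        pts = proj(pts) + pts.mean(axis=0)

    T = float(np.linalg.norm(M - E))
    u = (M - E) / T
    v = np.cross(normal, u)
    v /= np.linalg.norm(v)
    d = (pts - E) @ v                    # signed offset from the T-line
    end_side = np.sign(d[0] + d[-1])     # vessel ends lie opposite the apex
    side = -end_side if end_side != 0 else 1.0
    A = float(np.max(d * side))
    A = max(A, 0.0)

    P0, Pend = pts[0], pts[-1]
    if np.linalg.norm(B - P0) < 1e-12 or np.linalg.norm(Pend - S) < 1e-12 \
            or np.linalg.norm(B - S) < 1e-12:
        raise ValueError("degenerate chord: coincident landmark points")
    aao_dao = line_angle_deg(B - P0, Pend - S)
    tao_dao = ray_angle_deg(B - S, Pend - S)
    return {"height_A": A, "width_T": T, "at_ratio": A / T,
            "aao_dao_angle": aao_dao, "tao_dao_angle": tao_dao}


def classify_arch(at_ratio: float) -> str:
    """Height-to-width classification: gothic > 0.8, crenel < 0.6, else romanesque."""
    if not np.isfinite(at_ratio) or at_ratio <= 0:
        raise ValueError("A/T ratio must be positive")
    if at_ratio > GOTHIC_AT:
        return "gothic"
    if at_ratio < CRENEL_AT:
        return "crenel"
    return "romanesque"


def evaluate_criteria(m: ArchMeasurements, reference_diameter: float | None = None):
    """Hypoplasia flags on Di/AOA and the <=50%-of-reference coarctation flag.

    Hypoplasia thresholds (strict <): proximal arch 60%, distal arch 50%,
    isthmus 40% of the ascending-aorta diameter. The coarctation reference
    defaults to the mid-descending diameter D4.
    """
    haa = {
        "proximal": m.ratios["D1_AOA"] < HAA_THRESHOLDS["proximal"],
        "distal": m.ratios["D2_AOA"] < HAA_THRESHOLDS["distal"],
        "isthmus": m.ratios["D3_AOA"] < HAA_THRESHOLDS["isthmus"],
    }
    ref = reference_diameter if reference_diameter is not None else m.diameters["D4"]
    coa = bool(min(m.diameters.values()) <= COA_FRACTION * ref)
    return haa, coa


def measure_case(obj, landmarks=None, window: float = LEVEL_WINDOW) -> ArchMeasurements:
    """Full measurement record for one case (any supported geometry input).

    ``window`` is the physical (mm) search half-width of the level-diameter
    measurement; scale it together with the geometry when measuring
    rescaled data.
    """
    cl, lms = _resolve(obj, landmarks)
    diam = measure_diameters(cl, lms, window=window)
    geo = compute_arch_geometry(cl, lms)
    ratios = {f"D{i}_AOA": diam[f"D{i}"] / diam["AOA"] for i in range(1, 6)}
    m = ArchMeasurements(diameters=diam, ratios=ratios, **geo)
    m.arch_class = classify_arch(m.at_ratio)
    m.haa_flags, m.coa_flag = evaluate_criteria(m)
    return m
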