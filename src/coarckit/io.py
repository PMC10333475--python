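"""File formats, configuration and the pipeline driver.

Formats: NIfTI-1 binary masks (nibabel), CSV centerline polylines
(s_mm, x_mm, y_mm, z_mm, radius_mm), JSON landmark files (name -> world
xyz in mm), YAML cohort-summary specs (group -> variable -> {mean, sem}
plus n and categorical counts) and YAML network specs (mm geometry).
The shipped defaults encode the published three-group summary table and the
reference gothic coarctation network.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arch_synth import Centerline, GroupSummary, VoxelMask
from .hemodynamics import (ArterialNetwork, BoundaryConditions, FluidProps,
                           SolverSettings, Stenosis, VesselSegment)

GROUP_ORDER = ("gothic", "crenel", "romanesque")


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def write_mask(mask: VoxelMask, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_mask(path, landmarks=None) -> VoxelMask:
    import nibabel as nib

    img = nib.load(str(path))
    grid = np.asarray(img.dataobj)
    vals = np.unique(grid)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError(f"mask must be binary {{0,1}}, found values {vals[:6]}")
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("malformed header: affine rotation not axis-aligned "
                         "(field: affine)")
    spacing = np.diag(rot).copy()
    if np.any(spacing <= 0):
        raise ValueError("malformed header: non-positive voxel spacing "
                         "(field: pixdim)")
    return VoxelMask(grid=grid.astype(np.uint8), spacing=spacing,
                     origin=aff[:3, 3].copy(), landmarks=landmarks)


# ---------------------------------------------------------------------------
# centerlines and landmarks
# ---------------------------------------------------------------------------

def write_centerline_csv(cl: Centerline, path) -> None:
    df = pd.DataFrame({"s_mm": cl.s, "x_mm": cl.points[:, 0],
                       "y_mm": cl.points[:, 1], "z_mm": cl.points[:, 2],
                       "radius_mm": cl.radii})
    df.to_csv(path, index=False)


def read_centerline_csv(path) -> Centerline:
    df = pd.read_csv(path)
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    return Centerline(s=df["s_mm"].to_numpy(float), points=pts,
                      radii=df["radius_mm"].to_numpy(float))


def write_landmarks(landmarks: dict, path) -> None:
    """Landmark file: name -> world xyz (mm); accepts Landmark or points."""
    out = {}
    for name, v in landmarks.items():
        p = v.point if hasattr(v, "point") else np.asarray(v, float)
        out[name] = [float(c) for c in p]
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True))


def read_landmarks(path) -> dict:
    return {k: np.asarray(v, float)
            for k, v in json.loads(Path(path).read_text()).items()}


# ---------------------------------------------------------------------------
# cohort summary specs
# ---------------------------------------------------------------------------

def _summaries_from_spec(spec: dict) -> list:
    summaries = []
    order = [g for g in GROUP_ORDER if g in spec["groups"]] + \
            [g for g in spec["groups"] if g not in GROUP_ORDER]
    for label in order:
        g = spec["groups"][label]
        variables = {k: (float(v["mean"]), float(v["sem"]))
                     for k, v in g["variables"].items()}
        props = {k: float(c) / g["n"] for k, c in g.get("counts", {}).items()}
        summaries.append(GroupSummary(label=label, n=int(g["n"]),
                                      variables=variables, proportions=props))
    return summaries


def load_cohort_spec(path) -> list:
    """Group summaries from a YAML cohort spec."""
    return _summaries_from_spec(yaml.safe_load(Path(path).read_text()))


def load_published_cohort():
    """The shipped three-group summary: (summaries, printed-statistics dict)."""
    text = resources.files("coarckit.data").joinpath("cohort_table.yaml").read_text()
    spec = yaml.safe_load(text)
    return _summaries_from_spec(spec), spec["printed_statistics"]


# ---------------------------------------------------------------------------
# network specs
# ---------------------------------------------------------------------------

def _segment_from_spec(d: dict) -> VesselSegment:
    st = d.get("stenosis")
    sten = Stenosis(area_ratio=float(st["area_ratio"]),
                    length=float(st["length_mm"]) * 1e-3) if st else None
    return VesselSegment(name=d["name"], length=float(d["length_mm"]) * 1e-3,
                         d_prox=float(d["d_prox_mm"]) * 1e-3,
                         d_dist=float(d["d_dist_mm"]) * 1e-3, stenosis=sten)


def load_network(path=None):
    """(network, bcs, fluid, settings) from a YAML spec; default = shipped case."""
    if path is None:
        text = resources.files("coarckit.data").joinpath("gothic_coa.yaml").read_text()
    else:
        text = Path(path).read_text()
    spec = yaml.safe_load(text)
    net = ArterialNetwork(
        main=[_segment_from_spec(d) for d in spec["main_segments"]],
        branches=[(_segment_from_spec(d), int(d["attach_after"]))
                  for d in spec["branches"]])
    f = spec.get("fluid", {})
    fluid = FluidProps(density=f.get("density_kg_m3", 1050.0),
                       viscosity=f.get("viscosity_pa_s", 0.0035))
    b = spec.get("boundary", {})
    bcs = BoundaryConditions(
        v_peak=b.get("inlet_peak_velocity_m_s", 1.2),
        period=b.get("period_s", 0.8),
        systolic_fraction=b.get("systolic_fraction", 0.35),
        p_upper=b.get("upper_limb_pressure_mmhg", 120.0),
        p_lower=b.get("lower_limb_pressure_mmhg", 65.0))
    s = spec.get("solver", {})
    settings = SolverSettings(dt=s.get("dt_s", 0.005),
                              max_newton=s.get("max_newton_iterations", 200),
                              max_cycles=s.get("max_cycles", 10))
    return net, bcs, fluid, settings


# ---------------------------------------------------------------------------
# run configuration and pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    seed: int = 0
    spacing: float = 0.4           # mm, voxelization
    out_dir: str = "coarckit_out"
    cohort_spec: str | None = None  # default: shipped summary table
    network_spec: str | None = None
    calibrate_pspg: float | None = 57.2
    voxel_path: bool = False       # cohort measurement through masks
    thresholds: dict = field(default_factory=lambda: {
        "gothic": 0.8, "crenel": 0.6, "haa": [0.60, 0.50, 0.40],
        "coa": 0.50, "pspg": [20.0, 10.0]})

    def __post_init__(self):
        t = self.thresholds
        if not t["crenel"] < t["gothic"]:
            raise ValueError("classification thresholds must satisfy crenel < gothic")
        if not all(a > b for a, b in zip(t["haa"], t["haa"][1:])):
            raise ValueError("hypoplasia thresholds must be strictly decreasing")
        if not t["pspg"][0] > t["pspg"][1]:
            raise ValueError("PSPG thresholds must be decreasing")


def load_config(path) -> RunConfig:
    return RunConfig(**yaml.safe_load(Path(path).read_text()))


def _cmd_generate(config: RunConfig, out: Path) -> None:
    from .arch_synth import build_arch, sample_cohort_table

    summaries = (load_cohort_spec(config.cohort_spec)
                 if config.cohort_spec else load_published_cohort()[0])
    table, params = sample_cohort_table(summaries, config.seed)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(params):
        arch = build_arch(p)
        case = f"case{i:03d}"
        write_centerline_csv(arch.centerline, out / f"{case}_centerline.csv")
        write_landmarks(arch.landmarks, out / f"{case}_landmarks.json")
        rows.append({"case": case, "group": p.arch_type, "height_A": p.height_A,
                     "width_T": p.width_T, "at_ratio": p.at_ratio,
                     "aao_dao": p.aao_dao_angle, "tao_dao": p.tao_dao_angle,
                     **{f"{k}_mm": v for k, v in p.level_diameters.items()}})
    pd.DataFrame(rows).to_csv(out / "cohort_params.csv", index=False)
    table.insert(0, "case", [f"case{i:03d}" for i in range(len(table))])
    table.to_csv(out / "cohort_clinical.csv", index=False)


def _cmd_measure(config: RunConfig, out: Path) -> None:
    from .morphometry import measure_case

    params = pd.read_csv(out / "cohort_params.csv")
    rows = []
    for case, group in zip(params["case"], params["group"]):
        cl = read_centerline_csv(out / f"{case}_centerline.csv")
        lms = read_landmarks(out / f"{case}_landmarks.json")
        m = measure_case(cl, lms)
        rows.append({"case": case, "group": group, **m.as_row()})
    pd.DataFrame(rows).to_csv(out / "cohort_measurements.csv", index=False)


def _cmd_cohort_stats(config: RunConfig, out: Path) -> None:
    from .cohort_stats import build_group_table

    df = pd.read_csv(out / "cohort_measurements.csv")
    clin = pd.read_csv(out / "cohort_clinical.csv")
    merged = df.merge(clin.drop(columns=["group"], errors="ignore"), on="case")
    numeric = [c for c in ("age_months", "weight_kg", "pspg_mmhg",
                           "D1_AOA", "D2_AOA", "D3_AOA", "D4_AOA", "D5_AOA",
                           "AAO_DAO", "TAO_DAO", "A_T") if c in merged]
    cats = [c for c in ("male", "pda") if c in merged]
    table = build_group_table(merged, group_col="group", numeric=numeric,
                         categorical=cats, order=list(GROUP_ORDER))
    table.to_csv(out / "group_table_synthetic.csv", index=False)
    (out / "group_table_synthetic.md").write_text(table.to_markdown(index=False))


def _cmd_simulate(config: RunConfig, out: Path) -> None:
    from .hemodynamics import MMHG, calibrate_stenosis, extract_profiles, solve_pulsatile

    net, bcs, fluid, settings = load_network(config.network_spec)
    out.mkdir(parents=True, exist_ok=True)
    if config.calibrate_pspg:
        cal = calibrate_stenosis(net, bcs, fluid, settings,
                                 target_pspg=config.calibrate_pspg)
        res, net = cal.result, cal.network
        extra = {"calibrated_area_ratio": cal.area_ratio,
                 "bernoulli_pspg_mmhg": cal.bernoulli_pspg}
    else:
        res = solve_pulsatile(net, bcs, fluid, settings)
        extra = {}
    prof = extract_profiles(res)
    pd.DataFrame({
        "t_s": res.t, "v_in_m_s": res.v_in, "p_in_mmhg": res.p_in / MMHG,
        "q_bct_ml_s": res.q_branch[0] * 1e6, "q_lcca_ml_s": res.q_branch[1] * 1e6,
        "q_lsca_ml_s": res.q_branch[2] * 1e6,
        "q_desc_ml_s": res.seg_flows[-1] * 1e6,
    }).to_csv(out / "flow_timeseries.csv", index=False)
    pd.DataFrame({"x_mm": prof.x, "p_mmhg": prof.p, "v_m_s": prof.v}).to_csv(
        out / "axial_profile.csv", index=False)
    metrics = {k: v for k, v in prof.metrics.items()}
    metrics.update(extra)
    (out / "hemo_summary.json").write_text(
        json.dumps(metrics, indent=1, default=str, sort_keys=True))


COMMANDS = ("generate", "measure", "cohort-stats", "simulate", "report")


def run_pipeline(config: RunConfig, command: str) -> list:
    """Run one pipeline stage (or the full report); returns artifact paths.

    Deterministic for a fixed config + seed; all randomness descends from
    ``config.seed``.
    """
    out = Path(config.out_dir)
    if command == "generate":
        _cmd_generate(config, out)
    elif command == "measure":
        _cmd_measure(config, out)
    elif command == "cohort-stats":
        _cmd_cohort_stats(config, out)
    elif command == "simulate":
        _cmd_simulate(config, out)
    elif command == "report":
        _cmd_generate(config, out)
        _cmd_measure(config, out)
        _cmd_cohort_stats(config, out)
        _cmd_simulate(config, out)
    else:
        raise ValueError(f"unknown command {command!r}; expected one of {COMMANDS}")
    return sorted(p for p in out.iterdir() if p.is_file())
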