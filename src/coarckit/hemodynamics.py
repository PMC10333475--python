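"""Reduced-order pulsatile hemodynamics of the coarcted aortic arch.

A one-dimensional rigid-wall network model of the arch: inlet (ascending
aorta), three supra-aortic branch outlets (brachiocephalic trunk, LCCA,
LSCA) and the descending-aorta outlet. Blood is an incompressible Newtonian
fluid (density 1050 kg/m^3, dynamic viscosity 0.0035 Pa s), flow laminar;
each segment contributes viscous (Poiseuille over a linear taper),
convective (Bernoulli) and inertial (flow-acceleration) pressure losses,
and the coarctation itself is a Young-Tsai type stenosis element with
viscous, turbulent-expansion and inertial terms.

At each time step the nonlinear balance — prescribed inlet flow split over
the four outlet paths, each path matching its outlet pressure — is solved by
damped Newton iteration; cycles are marched until the inlet-pressure curve
is periodic and the last cycle is reported.

Internally SI units; interfaces use mmHg, m/s and (for geometry files) mm.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

MMHG = 133.322          # Pa per mmHg
RE_LAMINAR = 2300.0     # laminar-assumption threshold

#: Young-Tsai stenosis constants: turbulent expansion, inertial, and the
#: viscous prefactor K_v = 32 (L_s/D_0) (A_0/A_s)^2
KT = 1.52
KU = 1.2


@dataclass(frozen=True)
class FluidProps:
    density: float = 1050.0      # kg/m^3
    viscosity: float = 0.0035    # Pa s (dynamic)

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass
class Stenosis:
    area_ratio: float            # A_s / A_0, in (0, 1]
    length: float = 0.008        # m, throat length

    def __post_init__(self):
        if not (0.0 < self.area_ratio <= 1.0):
            raise ValueError("stenosis area ratio must lie in (0, 1]")
        if self.length <= 0:
            raise ValueError("stenosis length must be positive")


@dataclass
class VesselSegment:
    name: str
    length: float                # m
    d_prox: float                # m
    d_dist: float                # m
    stenosis: Stenosis | None = None
    cells: int = 8

    def __post_init__(self):
        if self.length <= 0 or self.d_prox <= 0 or self.d_dist <= 0:
            raise ValueError(f"segment {self.name}: non-positive geometry")
        if self.cells < 4:
            raise ValueError(f"segment {self.name}: need >= 4 cells")

    def diameter(self, x: float) -> float:
        return self.d_prox + (self.d_dist - self.d_prox) * x / self.length

    def area(self, x: float) -> float:
        return np.pi * self.diameter(x) ** 2 / 4.0

    @property
    def mean_diameter(self) -> float:
        return 0.5 * (self.d_prox + self.d_dist)

    def int_inv_d4(self) -> float:
        """integral dx / D(x)^4 over the (linearly tapered) segment."""
        d1, d2 = self.d_prox, self.d_dist
        if abs(d2 - d1) < 1e-12 * d1:
            return self.length / d1**4
        return self.length / (3.0 * (d2 - d1)) * (1.0 / d1**3 - 1.0 / d2**3)

    def int_inv_a(self) -> float:
        """integral dx / A(x) over the segment."""
        d1, d2 = self.d_prox, self.d_dist
        if abs(d2 - d1) < 1e-12 * d1:
            return self.length / (np.pi * d1**2 / 4.0)
        return 4.0 * self.length / (np.pi * d1 * d2)


def segment_pressure_loss(segment: VesselSegment, Q: float, dQdt: float,
                          fluid: FluidProps) -> float:
    """Proximal-to-distal pressure drop (Pa) of one segment at flow Q.

    viscous (Poiseuille integrated over the taper) + convective
    (1/2 rho (v_d^2 - v_p^2)) + inertial (rho dQ/dt int dx/A) + the
    Young-Tsai stenosis element when present.
    """
    rho, mu = fluid.density, fluid.viscosity
    dp = 128.0 * mu / np.pi * Q * segment.int_inv_d4()
    v_p = Q / segment.area(0.0)
    v_d = Q / segment.area(segment.length)
    # accelerating (nozzle) head follows Bernoulli; decelerating (diffuser)
    # head is treated as dissipated (no pressure recovery), which keeps the
    # path pressure loss monotone in the flow
    if Q >= 0:
        dp += 0.5 * rho * max(v_d**2 - v_p**2, 0.0)
    else:
        dp += -0.5 * rho * max(v_p**2 - v_d**2, 0.0)
    dp += rho * dQdt * segment.int_inv_a()
    st = segment.stenosis
    if st is not None:
        d0 = segment.mean_diameter
        a0 = np.pi * d0**2 / 4.0
        r = 1.0 / st.area_ratio          # A_0 / A_s >= 1
        v0 = Q / a0
        kv = 32.0 * (st.length / d0) * r**2
        dp += kv * mu * v0 / d0
        dp += 0.5 * KT * rho * (r - 1.0) ** 2 * v0 * abs(v0)
        dp += KU * rho * st.length * (dQdt / a0)
    return float(dp)


@dataclass
class ArterialNetwork:
    """Inlet -> ascending -> (BCT) -> (LCCA) -> (LSCA) -> isthmus -> descending.

    ``main`` is the inlet-to-descending path; ``branches`` are
    (segment, attach_after) pairs where ``attach_after`` is the index of the
    main segment whose distal node feeds the branch.
    """

    main: list
    branches: list = field(default_factory=list)

    def __post_init__(self):
        for _, attach in self.branches:
            if not (0 <= attach < len(self.main) - 1):
                raise ValueError("branch must attach at an interior junction")
        for seg_a, seg_b in zip(self.main, self.main[1:]):
            jump = abs(seg_b.d_prox - seg_a.d_dist) / seg_a.d_dist
            if jump > 0.20:
                raise ValueError(
                    f"diameter discontinuity {jump:.0%} between {seg_a.name} "
                    f"and {seg_b.name} exceeds 20%")

    @property
    def stenosed_index(self) -> int | None:
        for i, seg in enumerate(self.main):
            if seg.stenosis is not None:
                return i
        return None

    def main_flows(self, q_in: float, q_branch: np.ndarray) -> np.ndarray:
        """Flow carried by each main segment given the three branch flows."""
        flows = np.empty(len(self.main))
        taken = 0.0
        offtake = {attach: q for (_, attach), q in zip(
            [(b, a) for b, a in self.branches], q_branch)}
        for i in range(len(self.main)):
            flows[i] = q_in - taken
            if i in offtake:
                taken += offtake[i]
        return flows


@dataclass
class BoundaryConditions:
    v_peak: float = 1.2            # m/s, inlet peak velocity
    period: float = 0.8            # s, cardiac cycle
    systolic_fraction: float = 0.35
    p_upper: float = 120.0         # mmHg, arm-puncture pressure (3 branches)
    p_lower: float = 65.0          # mmHg, leg-puncture pressure (descending)
    waveform: str = "half-sine"    # or "constant" (steady inflow)

    def __post_init__(self):
        if self.v_peak < 0 or self.period <= 0:
            raise ValueError("need v_peak >= 0 and period > 0")
        if self.waveform not in ("half-sine", "constant"):
            raise ValueError("waveform must be 'half-sine' or 'constant'")
        for p in (self.p_upper, self.p_lower):
            if not (0.0 <= p <= 300.0):
                raise ValueError("outlet pressures must be physiologic (0-300 mmHg)")

    def v_in(self, t: float) -> float:
        """Half-sine systolic inflow with zero diastolic inflow, or steady."""
        if self.waveform == "constant":
            return self.v_peak
        ts = self.systolic_fraction * self.period
        tm = t % self.period
        return self.v_peak * np.sin(np.pi * tm / ts) if tm < ts else 0.0


@dataclass
class SolverSettings:
    dt: float = 0.005
    max_newton: int = 200
    max_cycles: int = 10
    cycle_tol: float = 1e-4
    newton_tol: float = 1e-6       # Pa, residual infinity-norm
    profile_cells: int = 24

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class HemoResult:
    t: np.ndarray                  # last-cycle times, s
    v_in: np.ndarray               # inlet velocity, m/s
    q_in: np.ndarray               # inlet flow, m^3/s
    p_in: np.ndarray               # inlet pressure, Pa
    q_branch: np.ndarray           # (3, n) branch flows
    seg_flows: np.ndarray          # (n_main, n)
    seg_dqdt: np.ndarray           # (n_main, n)
    network: ArterialNetwork = None
    bcs: BoundaryConditions = None
    fluid: FluidProps = None
    settings: SolverSettings = None
    cycles: int = 0
    mass_residual: float = 0.0
    retrograde: bool = False
    periodic: bool = False

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.v_in))

    def reynolds(self) -> dict:
        """Per-segment maximum Reynolds number over the cycle."""
        rho, mu = self.fluid.density, self.fluid.viscosity
        out = {}
        for i, seg in enumerate(self.network.main):
            d = seg.mean_diameter
            if seg.stenosis is not None:
                d_throat = d * np.sqrt(seg.stenosis.area_ratio)
                v = np.abs(self.seg_flows[i]) / (np.pi * d_throat**2 / 4.0)
                out[seg.name] = float(np.max(rho * v * d_throat / mu))
            else:
                v = np.abs(self.seg_flows[i]) / (np.pi * d**2 / 4.0)
                out[seg.name] = float(np.max(rho * v * d / mu))
        for (seg, _), q in zip(self.network.branches, self.q_branch):
            d = seg.mean_diameter
            v = np.abs(q) / (np.pi * d**2 / 4.0)
            out[seg.name] = float(np.max(rho * v * d / mu))
        return out

    def laminar_violations(self) -> list:
        return [k for k, re in self.reynolds().items() if re > RE_LAMINAR]


# ---------------------------------------------------------------------------
# clinical calculators
# ---------------------------------------------------------------------------

def bernoulli_gradient(v_jet: float, v_prox: float = 0.0, mode: str = "simplified",
                       fluid: FluidProps = FluidProps()) -> float:
    """Transstenotic gradient (mmHg) from jet velocity, Bernoulli form.

    ``simplified``: 4 (v_jet^2 - v_prox^2), the clinical Doppler formula;
    ``full``: 1/2 rho (v_jet^2 - v_prox^2) Pa converted at 133.322 Pa/mmHg.
    """
    if v_prox < 0 or v_jet < v_prox:
        raise ValueError("need v_jet >= v_prox >= 0")
    if mode == "simplified":
        return 4.0 * (v_jet**2 - v_prox**2)
    if mode == "full":
        return 0.5 * fluid.density * (v_jet**2 - v_prox**2) / MMHG
    raise ValueError("mode must be 'simplified' or 'full'")


def jet_velocity(v_in: float, area_ratio: float) -> float:
    """Continuity: jet velocity for a proximal-to-throat area ratio >= 1."""
    if area_ratio < 1.0:
        raise ValueError("area ratio A_0/A_s must be >= 1")
    return v_in * area_ratio


def pspg_criteria(pspg: float, collaterals_present: bool = False) -> bool:
    """Coarctation diagnosis from the peak systolic pressure gradient.

    Positive above 20 mmHg, or above 10 mmHg when significant collateral
    circulation is present.
    """
    if pspg < 0:
        raise ValueError("PSPG must be non-negative")
    return pspg > 20.0 or (pspg > 10.0 and collaterals_present)


# ---------------------------------------------------------------------------
# the pulsatile solve
# ---------------------------------------------------------------------------

def _residuals(network, q_in, x, prev_flows, dt, fluid, p_out):
    """Residuals (Pa) of the outlet-path pressure balances.

    x = [branch flows..., p_in]; the descending flow is q_in minus the
    branch flows, so mass is conserved identically.
    """
    qb = x[:-1]
    p_in = x[-1]
    flows = network.main_flows(q_in, qb)
    dqdt = (flows - prev_flows[:len(flows)]) / dt
    # cumulative drop down the main path at each junction node
    drops = np.concatenate([[0.0], np.cumsum([
        segment_pressure_loss(seg, flows[i], dqdt[i], fluid)
        for i, seg in enumerate(network.main)])])
    res = np.empty(len(qb) + 1)
    for b, ((seg, attach), q) in enumerate(zip(network.branches, qb)):
        dq = (q - prev_flows[len(network.main) + b]) / dt
        loss = segment_pressure_loss(seg, q, dq, fluid)
        res[b] = p_in - drops[attach + 1] - loss - p_out[b]
    res[-1] = p_in - drops[-1] - p_out[-1]
    return res, flows, dqdt


def solve_pulsatile(network: ArterialNetwork, bcs: BoundaryConditions = None,
                    fluid: FluidProps = None, settings: SolverSettings = None) -> HemoResult:
    """March the pulsatile network to a periodic state and return the last cycle."""
    bcs = bcs or BoundaryConditions()
    fluid = fluid or FluidProps()
    settings = settings or SolverSettings()
    n = int(round(bcs.period / settings.dt))
    if abs(n * settings.dt - bcs.period) > 1e-9 * bcs.period:
        raise ValueError("dt must divide the cardiac period")
    if n < 20:
        raise ValueError("dt too coarse to resolve the inflow waveform")

    a_in = network.main[0].area(0.0)
    nm = len(network.main)
    nb = len(network.branches)
    p_out = np.array([bcs.p_upper] * nb + [bcs.p_lower]) * MMHG
    t_grid = np.arange(n) * settings.dt
    v_grid = np.array([bcs.v_in(t) for t in t_grid])
    q_grid = a_in * v_grid

    q_scale = max(a_in * max(bcs.v_peak, 0.1), 1e-8)
    scale = np.concatenate([np.full(nb, q_scale), [100.0 * MMHG]])

    x = np.concatenate([np.full(nb, 0.5 * q_scale / max(nb, 1)),
                        [bcs.p_upper * MMHG]])
    prev_flows = np.zeros(nm + nb)
    prev_p_in = None
    keep = None

    periodic = False
    for cycle in range(settings.max_cycles):
        p_in_c = np.empty(n)
        q_branch_c = np.empty((nb, n))
        seg_flows_c = np.empty((nm, n))
        seg_dqdt_c = np.empty((nm, n))
        for k in range(n):
            q_in = q_grid[k]

            def fun(xv):
                return _residuals(network, q_in, xv, prev_flows, settings.dt,
                                  fluid, p_out)

            def newton(x0):
                """Damped Newton with stall detection; returns (x, converged)."""
                xl = x0.copy()
                r, *_ = fun(xl)
                history = []
                for _ in range(settings.max_newton):
                    rmax = np.max(np.abs(r))
                    if rmax <= settings.newton_tol:
                        return xl, True
                    history.append(rmax)
                    if len(history) > 8 and history[-8] < 1.01 * rmax:
                        return xl, False          # stalled in a local minimum
                    nun = len(xl)
                    J = np.empty((nun, nun))
                    for j in range(nun):
                        xp = xl.copy()
                        h = 1e-7 * scale[j]
                        xp[j] += h
                        J[:, j] = (fun(xp)[0] - r) / h
                    try:
                        step = np.linalg.solve(J, -r)
                    except np.linalg.LinAlgError:
                        step = np.linalg.lstsq(J, -r, rcond=None)[0]
                    alpha, r0 = 1.0, np.linalg.norm(r)
                    while alpha > 1.0 / 1024.0:
                        if np.linalg.norm(fun(xl + alpha * step)[0]) < r0:
                            break
                        alpha *= 0.5
                    xl = xl + alpha * step
                    r, *_ = fun(xl)
                return xl, bool(np.max(np.abs(r)) <= settings.newton_tol)

            starts = [x,
                      np.concatenate([np.full(nb, 0.2 * q_in),
                                      [bcs.p_upper * MMHG]]),
                      np.concatenate([np.full(nb, -0.07 * q_scale),
                                      [bcs.p_upper * MMHG]])]
            solved = False
            for x0 in starts:
                x_try, ok = newton(x0)
                if ok:
                    x, solved = x_try, True
                    break
                # polish a stalled iterate with MINPACK's dogleg, then Newton
                from scipy.optimize import root

                sol = root(lambda u: fun(u * scale)[0], x_try / scale, method="hybr")
                x_try, ok = newton(sol.x * scale)
                if ok:
                    x, solved = x_try, True
                    break
            if not solved:
                r_now = np.max(np.abs(fun(x_try)[0]))
                raise RuntimeError(
                    f"Newton failed at t={t_grid[k]:.3f}s: residual "
                    f"{r_now:.3e} Pa after {settings.max_newton} iterations")
            r, flows, dqdt = fun(x)
            qb = x[:-1]
            p_in_c[k] = x[-1]
            q_branch_c[:, k] = qb
            seg_flows_c[:, k] = flows
            seg_dqdt_c[:, k] = dqdt
            prev_flows = np.concatenate([flows, qb])
        keep = (p_in_c, q_branch_c, seg_flows_c, seg_dqdt_c)
        if prev_p_in is not None:
            delta = np.max(np.abs(p_in_c - prev_p_in)) / max(np.max(np.abs(p_in_c)), 1.0)
            if delta < settings.cycle_tol:
                periodic = True
                break
        prev_p_in = p_in_c.copy()
    cycles_run = cycle + 1

    p_in_c, q_branch_c, seg_flows_c, seg_dqdt_c = keep
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(q_grid - (q_branch_c.sum(axis=0) + seg_flows_c[-1])) / np.abs(q_grid)
    mass = float(np.nanmax(np.where(q_grid != 0, rel, 0.0)))
    return HemoResult(
        t=t_grid, v_in=v_grid, q_in=q_grid, p_in=p_in_c, q_branch=q_branch_c,
        seg_flows=seg_flows_c, seg_dqdt=seg_dqdt_c, network=network, bcs=bcs,
        fluid=fluid, settings=settings, cycles=cycles_run, mass_residual=mass,
        retrograde=bool((seg_flows_c[-1] < -1e-12).any()), periodic=periodic)


# ---------------------------------------------------------------------------
# profiles and calibration
# ---------------------------------------------------------------------------

@dataclass
class AxialProfile:
    x: np.ndarray          # mm along the inlet->descending path
    p: np.ndarray          # mmHg, peak systole
    v: np.ndarray          # m/s, peak systole
    metrics: dict


def throat_velocity(result: HemoResult) -> np.ndarray:
    """Velocity in the stenosis throat over the last cycle (m/s)."""
    i = result.network.stenosed_index
    if i is None:
        raise ValueError("network has no stenosis")
    seg = result.network.main[i]
    a_throat = (np.pi * seg.mean_diameter**2 / 4.0) * seg.stenosis.area_ratio
    return result.seg_flows[i] / a_throat


def extract_profiles(result: HemoResult) -> AxialProfile:
    """Peak-systolic axial pressure/velocity curve and its summary metrics.

    The transstenotic gradient is read between the pre-stenotic node (the
    junction feeding the stenosed segment) and the mid-descending station.
    """
    net, fluid, settings = result.network, result.fluid, result.settings
    k = result.peak_index
    ncell = settings.profile_cells
    x_mm, p_pa, v_ms = [0.0], [result.p_in[k]], [result.seg_flows[0][k] / net.main[0].area(0.0)]
    node_pressures = [result.p_in[k]]
    x0 = 0.0
    for i, seg in enumerate(net.main):
        Q = result.seg_flows[i][k]
        dqdt = result.seg_dqdt[i][k]
        edges = np.linspace(0.0, seg.length, ncell + 1)
        st = seg.stenosis
        extra = 0.0
        if st is not None:
            plain = segment_pressure_loss(
                VesselSegment(seg.name, seg.length, seg.d_prox, seg.d_dist,
                              cells=seg.cells), Q, dqdt, fluid)
            extra = segment_pressure_loss(seg, Q, dqdt, fluid) - plain
            lo = 0.5 * seg.length - 0.5 * st.length
            hi = 0.5 * seg.length + 0.5 * st.length
        p = p_pa[-1]
        for a, b in zip(edges, edges[1:]):
            sub = VesselSegment(seg.name, b - a, seg.diameter(a), seg.diameter(b),
                                cells=4)
            dp = segment_pressure_loss(sub, Q, dqdt, fluid)
            if st is not None:
                ov = max(0.0, min(b, hi) - max(a, lo))
                dp += extra * ov / st.length
            p -= dp
            xm = 0.5 * (a + b)
            in_throat = st is not None and lo <= xm <= hi
            area = seg.area(xm) * (st.area_ratio if in_throat else 1.0)
            x_mm.append((x0 + b) * 1000.0)
            p_pa.append(p)
            v_ms.append(Q / area)
        node_pressures.append(p)
        x0 += seg.length
    x_mm = np.asarray(x_mm)
    p_mmhg = np.asarray(p_pa) / MMHG
    v_ms = np.asarray(v_ms)

    isten = net.stenosed_index
    metrics = {"peak_time_s": float(result.t[k]), "cycles": result.cycles}
    if isten is not None:
        seg = net.main[isten]
        pre = node_pressures[isten] / MMHG
        # descending station: mid-descending (the last main segment)
        x_desc_lo = sum(s.length for s in net.main[:-1])
        mid = x_desc_lo + net.main[-1].length / 2.0
        i_mid = int(np.argmin(np.abs(x_mm - mid * 1000.0)))
        metrics["transstenotic_dp_mmhg"] = float(pre - p_mmhg[i_mid])
        vj = throat_velocity(result)
        metrics["peak_jet_velocity_ms"] = float(np.max(vj))
        metrics["bernoulli_pspg_mmhg"] = bernoulli_gradient(float(np.max(vj)))
        # sharpest pressure fall should sit in the throat cell range
        dpdx = np.diff(p_mmhg) / np.diff(x_mm)
        j = int(np.argmin(dpdx))
        metrics["max_gradient_x_mm"] = float(0.5 * (x_mm[j] + x_mm[j + 1]))
        x_sten_lo = sum(s.length for s in net.main[:isten])
        metrics["throat_span_mm"] = (
            (x_sten_lo + 0.5 * seg.length - 0.5 * seg.stenosis.length) * 1000.0,
            (x_sten_lo + 0.5 * seg.length + 0.5 * seg.stenosis.length) * 1000.0)
        # proximal (pre-stenotic) velocity extrema at peak systole
        pre_cells = (np.asarray(x_mm[1:]) <= x_sten_lo * 1000.0)
        vprox = np.abs(v_ms[1:][pre_cells])
        metrics["proximal_velocity_max_ms"] = float(vprox.max())
        metrics["proximal_plateau_mmhg"] = float(p_mmhg[0])
    metrics["reynolds_max"] = result.reynolds()
    metrics["laminar_violations"] = result.laminar_violations()
    return AxialProfile(x=x_mm, p=p_mmhg, v=v_ms, metrics=metrics)


@dataclass
class CalibrationResult:
    network: ArterialNetwork
    result: HemoResult
    area_ratio: float              # calibrated A_s/A_0
    bernoulli_pspg: float          # mmHg, from the peak jet velocity
    iterations: int


def calibrate_stenosis(network: ArterialNetwork, bcs: BoundaryConditions = None,
                       fluid: FluidProps = None, settings: SolverSettings = None,
                       target_pspg: float = 57.2, tol_mmhg: float = 0.1,
                       bounds: tuple = (1.05, 50.0)) -> CalibrationResult:
    """Bisect the throat constriction so the simplified-Bernoulli gradient
    from the solver's peak jet velocity matches the Doppler PSPG target.

    The bisection variable is the constriction A_0/A_s within ``bounds``.
    """
    if target_pspg <= 0:
        raise ValueError("target PSPG must be positive")
    isten = network.stenosed_index
    if isten is None:
        raise ValueError("network template has no stenosis element to calibrate")

    def run(r):
        net = copy.deepcopy(network)
        net.main[isten].stenosis.area_ratio = 1.0 / r
        res = solve_pulsatile(net, bcs, fluid, settings)
        vj = float(np.max(throat_velocity(res)))
        return net, res, bernoulli_gradient(vj)

    lo, hi = bounds
    _, _, g_lo = run(lo)
    _, _, g_hi = run(hi)
    if (g_lo - target_pspg) * (g_hi - target_pspg) > 0:
        raise ValueError(
            f"target {target_pspg} mmHg unreachable: gradient spans "
            f"[{min(g_lo, g_hi):.2f}, {max(g_lo, g_hi):.2f}] mmHg over "
            f"constriction bounds {bounds}")
    it = 2
    net = res = None
    g_mid = np.inf
    while it < 60:
        mid = 0.5 * (lo + hi)
        net, res, g_mid = run(mid)
        it += 1
        if abs(g_mid - target_pspg) <= tol_mmhg or (hi - lo) < 1e-6:
            break
        if (g_mid - target_pspg) * (g_lo - target_pspg) > 0:
            lo, g_lo = mid, g_mid
        else:
            hi = mid
    return CalibrationResult(network=net, result=res,
                             area_ratio=net.main[isten].stenosis.area_ratio,
                             bernoulli_pspg=g_mid, iterations=it)


# ---------------------------------------------------------------------------
# default gothic coarctation network
# ---------------------------------------------------------------------------

def network_from_params(params=None, area_ratio: float = 0.25) -> ArterialNetwork:
    """Build the 1-D network from an arch phantom's junction geometry.

    Segment lengths follow the phantom's arc lengths between junction
    landmarks and diameters follow its radius profile, so junction diameters
    are continuous by construction. ``area_ratio`` seeds the isthmus
    stenosis element (A_s/A_0); calibration replaces it.
    """
    from .arch_synth import build_arch, default_network_case

    params = params or default_network_case()
    arch = build_arch(params)
    lm = arch.landmarks
    cl = arch.centerline
    nodes = ["ascending_start", "brachiocephalic_anterior", "left_common_carotid",
             "lscA_posterior", "descending_start", "descending_end"]
    names = ["ascending", "proximal_arch", "distal_arch", "isthmus", "descending"]
    mm = 1e-3
    main = []
    for name, a, b in zip(names, nodes, nodes[1:]):
        sa, sb = lm[a].s, lm[b].s
        seg = VesselSegment(
            name=name, length=(sb - sa) * mm,
            d_prox=2 * float(cl.radius_at(sa)) * mm,
            d_dist=2 * float(cl.radius_at(sb)) * mm,
            stenosis=Stenosis(area_ratio=area_ratio) if name == "isthmus" else None)
        main.append(seg)
    branches = []
    for i, (key, attach) in enumerate(
            [("brachiocephalic", 0), ("LCCA", 1), ("LSCA", 2)]):
        d = params.branch_diameters[key] * mm
        branches.append((VesselSegment(name=key, length=0.025,
                                       d_prox=d, d_dist=0.85 * d), attach))
    return ArterialNetwork(main=main, branches=branches)


def default_coa_network(area_ratio: float = 0.25) -> ArterialNetwork:
    """The gothic coarctation reference network used by the worked example."""
    return network_from_params(None, area_ratio=area_ratio)
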