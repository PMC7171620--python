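"""Closed-loop lumped-parameter model of the whole-body circulation.

Four heart chambers are time-varying elastance elements,

    P(t) = E(t) (V - V0) - R_s Q,        R_s = K_s E(t) (V - V0),

with chamber volumes driven by flow balance dV/dt = Q_in - Q_out.  The four
valves (aortic, mitral, pulmonary, tricuspid) are diode + resistance +
inertance elements: while open,

    L dQ/dt = P_in - P_out - R Q,

opening when the upstream pressure exceeds the downstream pressure and
closing when the integrated flow turns negative (the flow is clamped at
zero).  The systemic and pulmonary arterial trees are three-element
Windkessel compartments,

    dP/dt = R_p dQ/dt + Q (R_p + R_d) / (R_d C) - (P - P_ven) / (R_d C),

and the venous returns are two-element Windkessel compartments
dP_ven/dt = Q_in/C - (P_ven - P_atrium)/(R_ven C).  Units follow clinical
convention: mmHg, mL, s (resistances mmHg*s/mL, compliances mL/mmHg,
elastances mmHg/mL, inertances mmHg*s^2/mL).

The elastance waveform (not prescribed by the Windkessel/elastance framework
itself) is a normalised double-Hill product with exponents 1.9 and 21.9,
time-scaled so its peak lands exactly at the requested time-at-maximum-
elastance.  Integration is fixed-step RK4, run cycle by cycle until the state
at cycle start is periodic to tolerance; the inner loop is numba-compiled,
with a pure-Python twin of the right-hand side kept for oracle testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from numba import njit

__all__ = [
    "WBCParameters",
    "WBCState",
    "MeasurementVector",
    "TargetVector",
    "SimulationResult",
    "IntegrationError",
    "DegeneratePhysiologyError",
    "normalized_elastance",
    "chamber_pressure",
    "windkessel3_dpdt",
    "windkessel2_dpdt",
    "derivatives",
    "simulate",
    "simulate_measurements_batch",
    "extract_measurements",
    "targets_from_params",
    "MEASUREMENT_NAMES",
    "TARGET_NAMES",
]


class IntegrationError(RuntimeError):
    pass


class DegeneratePhysiologyError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# elastance waveform
# ---------------------------------------------------------------------------

_DH_N1 = 1.9
_DH_N2 = 21.9
_DH_A1 = 0.303
_DH_A2 = 0.508
ATRIAL_OFFSET_FRAC = 0.12  # atrial activation precedes ventricular by 0.12 T
ATRIAL_TAU_FRAC = 0.10  # atrial time-to-peak within its own activation phase


def _double_hill_raw(x):
    x = np.asarray(x, dtype=float)
    h1 = (x / _DH_A1) ** _DH_N1
    return (h1 / (1.0 + h1)) / (1.0 + (x / _DH_A2) ** _DH_N2)


def _peak_of_raw():
    grid = np.linspace(0.0, 1.0, 200_001)
    vals = _double_hill_raw(grid)
    i = int(np.argmax(vals))
    return float(grid[i]), float(vals[i])


_DH_TPEAK, _DH_PEAKVAL = _peak_of_raw()


def normalized_elastance(t_norm, tau_max_norm):
    """Normalised activation waveform e in [0, 1] on one cycle.

    Single-peaked with its maximum (value 1) at ``t_norm == tau_max_norm``;
    essentially zero in late diastole.  The double-Hill argument is
    time-scaled so the peak lands exactly at the requested fraction.
    """
    t_norm = np.asarray(t_norm, dtype=float)
    s = _DH_TPEAK / float(tau_max_norm)
    return _double_hill_raw(t_norm * s) / _DH_PEAKVAL


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------


@dataclass
class WBCParameters:
    """Baseline values describe a resting healthy adult."""

    # chambers: maximum/minimum elastance (mmHg/mL), dead volume (mL),
    # source-resistance constant (dimensionless), time at max elastance (s)
    lv_emax: float = 2.5
    lv_emin: float = 0.08
    lv_v0: float = 15.0
    lv_ks: float = 5e-5
    lv_tau: float = 0.27
    rv_emax: float = 0.6
    rv_emin: float = 0.045
    rv_v0: float = 12.0
    rv_ks: float = 5e-5
    rv_tau: float = 0.27
    la_emax: float = 0.45
    la_emin: float = 0.12
    la_v0: float = 8.0
    la_ks: float = 5e-5
    la_tau: float = 0.09
    ra_emax: float = 0.35
    ra_emin: float = 0.10
    ra_v0: float = 6.0
    ra_ks: float = 5e-5
    ra_tau: float = 0.09
    # valves: aortic, pulmonary, mitral, tricuspid (mmHg*s/mL, mmHg*s^2/mL)
    av_r: float = 0.004
    av_l: float = 4e-4
    pulv_r: float = 0.003
    pulv_l: float = 3e-4
    mv_r: float = 0.003
    mv_l: float = 3e-4
    tv_r: float = 0.0025
    tv_l: float = 3e-4
    # systemic arterial (three-element Windkessel) and venous (two-element)
    rsys_p: float = 0.06
    rsys_d: float = 1.05
    csys: float = 1.3
    csysven: float = 20.0
    rsysven: float = 0.05
    # pulmonary analogues
    rpul_p: float = 0.008
    rpul_d: float = 0.07
    cpul: float = 4.5
    cpulven: float = 8.0
    rpulven: float = 0.008
    # heart period (s)
    T: float = 0.9

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"{f.name} is not finite")
        positives = [f.name for f in fields(self) if not f.name.endswith(("_v0", "_ks"))]
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for ch in ("lv", "rv", "la", "ra"):
            if getattr(self, f"{ch}_emax") <= getattr(self, f"{ch}_emin"):
                raise ValueError(f"{ch}: need E_max > E_min")
            if getattr(self, f"{ch}_v0") < 0:
                raise ValueError(f"{ch}: V0 must be >= 0")


@dataclass
class WBCState:
    """Dynamic state: chamber volumes, compartment pressures, valve flows."""

    v_lv: float
    v_rv: float
    v_la: float
    v_ra: float
    p_ao: float
    p_pa: float
    p_sysven: float
    p_pulven: float
    q_av: float
    q_pulv: float
    q_mv: float
    q_tv: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.v_lv, self.v_rv, self.v_la, self.v_ra,
             self.p_ao, self.p_pa, self.p_sysven, self.p_pulven,
             self.q_av, self.q_pulv, self.q_mv, self.q_tv]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "WBCState":
        return cls(*[float(v) for v in y])


MEASUREMENT_NAMES = [
    "p_ao_sys", "p_ao_edp", "lv_edv", "lv_esv", "lv_et",
    "p_pa_sys", "p_pa_edp", "rv_edv", "rv_esv", "rv_et",
]

TARGET_NAMES = [
    "sys_v0", "sys_tau_max", "sys_resistance", "sys_compliance", "sys_ratio", "sys_emax",
    "pul_v0", "pul_tau_max", "pul_resistance", "pul_compliance", "pul_ratio", "pul_emax",
]


@dataclass
class MeasurementVector:
    """Clinically measurable summary of one cardiac cycle."""

    p_ao_sys: float
    p_ao_edp: float
    lv_edv: float
    lv_esv: float
    lv_et: float
    p_pa_sys: float
    p_pa_edp: float
    rv_edv: float
    rv_esv: float
    rv_et: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MEASUREMENT_NAMES])

    def check(self, T: float) -> None:
        if not self.p_ao_sys > self.p_ao_edp:
            raise DegeneratePhysiologyError("systolic must exceed end-diastolic pressure")
        if not self.p_pa_sys > self.p_pa_edp:
            raise DegeneratePhysiologyError("systolic must exceed end-diastolic pressure")
        if not (self.lv_edv > self.lv_esv and self.rv_edv > self.rv_esv):
            raise DegeneratePhysiologyError("EDV must exceed ESV")
        if not (0.0 < self.lv_et < T and 0.0 < self.rv_et < T):
            raise DegeneratePhysiologyError("ejection time must lie inside the cycle")


@dataclass
class TargetVector:
    """Model parameters a surrogate regressor is trained to recover."""

    values: np.ndarray  # ordered per TARGET_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12,):
            raise ValueError("target vector has 12 components")
        if np.any(self.values <= 0):
            raise ValueError("target quantities must be positive")

    def as_array(self) -> np.ndarray:
        return self.values


def targets_from_params(params: WBCParameters) -> TargetVector:
    return TargetVector(np.array([
        params.lv_v0, params.lv_tau, params.rsys_p + params.rsys_d, params.csys,
        params.rsys_p / params.rsys_d, params.lv_emax,
        params.rv_v0, params.rv_tau, params.rpul_p + params.rpul_d, params.cpul,
        params.rpul_p / params.rpul_d, params.rv_emax,
    ]))


# ---------------------------------------------------------------------------
# physics pieces (pure Python; also the oracle for the compiled core)
# ---------------------------------------------------------------------------


@njit(cache=True)
def chamber_pressure(E: float, V: float, V0: float, Ks: float, Q: float) -> float:
    """P = E (V - V0) - R_s Q with the flow-dependent source resistance
    R_s = K_s E (V - V0)."""
    ev = E * (V - V0)
    return ev - Ks * ev * Q


def windkessel3_dpdt(p, q, dqdt, rp, rd, c, pven):
    """Three-element Windkessel pressure dynamics at the proximal node."""
    return rp * dqdt + q * (rp + rd) / (rd * c) - (p - pven) / (rd * c)


def windkessel2_dpdt(p, q_in, r, c, p_down):
    """Two-element (compliance + resistance) venous compartment."""
    return q_in / c - (p - p_down) / (r * c)


_PAR_FIELDS = [
    "lv_v0", "lv_ks", "rv_v0", "rv_ks", "la_v0", "la_ks", "ra_v0", "ra_ks",
    "av_r", "av_l", "pulv_r", "pulv_l", "mv_r", "mv_l", "tv_r", "tv_l",
    "rsys_p", "rsys_d", "csys", "csysven", "rsysven",
    "rpul_p", "rpul_d", "cpul", "cpulven", "rpulven",
]


def _pack(params: WBCParameters) -> np.ndarray:
    return np.array([getattr(params, n) for n in _PAR_FIELDS])


def _chamber_elastances(params: WBCParameters, t: float) -> np.ndarray:
    """E(t) for LV, RV, LA, RA at absolute time t (atria phase-advanced)."""
    tn = (t / params.T) % 1.0
    ta = (tn + ATRIAL_OFFSET_FRAC) % 1.0
    out = np.empty(4)
    out[0] = params.lv_emin + (params.lv_emax - params.lv_emin) * normalized_elastance(
        tn, params.lv_tau / params.T)
    out[1] = params.rv_emin + (params.rv_emax - params.rv_emin) * normalized_elastance(
        tn, params.rv_tau / params.T)
    out[2] = params.la_emin + (params.la_emax - params.la_emin) * normalized_elastance(
        ta, params.la_tau / params.T)
    out[3] = params.ra_emin + (params.ra_emax - params.ra_emin) * normalized_elastance(
        ta, params.ra_tau / params.T)
    return out


def derivatives(state: WBCState, params: WBCParameters, t: float) -> np.ndarray:
    """Time derivative of the 12-component state vector (reference path).

    A valve conducts when its flow is positive or its upstream pressure
    exceeds the downstream pressure; otherwise its flow derivative is zero
    (the integrator clamps negative flows to zero after each step).
    """
    y = state.as_array() if isinstance(state, WBCState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite state")
    e = _chamber_elastances(params, t)
    par = _pack(params)
    dy = np.empty(12)
    _rhs_py(y, e, par, dy)
    return dy


def _rhs_py(y, e, par, dy):
    """Python twin of the compiled right-hand side (kept in lockstep)."""
    vlv, vrv, vla, vra = y[0], y[1], y[2], y[3]
    pao, ppa, psv, ppv = y[4], y[5], y[6], y[7]
    qav, qpv, qmv, qtv = y[8], y[9], y[10], y[11]

    plv = chamber_pressure(e[0], vlv, par[0], par[1], qav)
    prv = chamber_pressure(e[1], vrv, par[2], par[3], qpv)
    pla = chamber_pressure(e[2], vla, par[4], par[5], qmv)
    pra = chamber_pressure(e[3], vra, par[6], par[7], qtv)

    dqav = (plv - pao - par[8] * qav) / par[9] if (qav > 0.0 or plv > pao) else 0.0
    dqpv = (prv - ppa - par[10] * qpv) / par[11] if (qpv > 0.0 or prv > ppa) else 0.0
    dqmv = (pla - plv - par[12] * qmv) / par[13] if (qmv > 0.0 or pla > plv) else 0.0
    dqtv = (pra - prv - par[14] * qtv) / par[15] if (qtv > 0.0 or pra > prv) else 0.0

    rsys_p, rsys_d, csys, csysven, rsysven = par[16], par[17], par[18], par[19], par[20]
    rpul_p, rpul_d, cpul, cpulven, rpulven = par[21], par[22], par[23], par[24], par[25]

    q_sys_cap = (pao - rsys_p * qav - psv) / rsys_d
    q_pul_cap = (ppa - rpul_p * qpv - ppv) / rpul_d
    q_ra_in = (psv - pra) / rsysven
    q_la_in = (ppv - pla) / rpulven

    dy[0] = qmv - qav
    dy[1] = qtv - qpv
    dy[2] = q_la_in - qmv
    dy[3] = q_ra_in - qtv
    dy[4] = rsys_p * dqav + qav * (rsys_p + rsys_d) / (rsys_d * csys) - (pao - psv) / (rsys_d * csys)
    dy[5] = rpul_p * dqpv + qpv * (rpul_p + rpul_d) / (rpul_d * cpul) - (ppa - ppv) / (rpul_d * cpul)
    dy[6] = (q_sys_cap - q_ra_in) / csysven
    dy[7] = (q_pul_cap - q_la_in) / cpulven
    dy[8] = dqav
    dy[9] = dqpv
    dy[10] = dqmv
    dy[11] = dqtv


_rhs = njit(cache=True)(_rhs_py)


@njit(cache=True)
def _total_volume(y, par):
    # stored volume: chambers + compliance * pressure at each storage node;
    # the arterial compliance sits behind the proximal resistance
    return (
        y[0] + y[1] + y[2] + y[3]
        + par[18] * (y[4] - par[16] * y[8])
        + par[19] * y[6]
        + par[23] * (y[5] - par[21] * y[9])
        + par[24] * y[7]
    )


@njit(cache=True)
def _one_cycle(y, par, Etab, N, dt, stats, traj, openrec, record):
    """Integrate one cardiac cycle in place, streaming cycle statistics.

    stats layout: [p_ao_sys, p_ao_edp, lv_edv, lv_esv, lv_et,
                   p_pa_sys, p_pa_edp, rv_edv, rv_esv, rv_et,
                   p_ao_mean, vol_start, vol_end]
    """
    k1 = np.empty(12)
    k2 = np.empty(12)
    k3 = np.empty(12)
    k4 = np.empty(12)
    yt = np.empty(12)

    pao_max = -1e30
    ppa_max = -1e30
    lv_max = -1e30
    lv_min = 1e30
    rv_max = -1e30
    rv_min = 1e30
    lv_et = 0.0
    rv_et = 0.0
    pao_sum = 0.0
    pao_edp = np.nan
    ppa_edp = np.nan
    av_prev = y[8] > 0.0
    pv_prev = y[9] > 0.0
    stats[11] = _total_volume(y, par)

    if record:
        for i in range(12):
            traj[0, i] = y[i]
        for v in range(4):
            openrec[0, v] = 1.0 if y[8 + v] > 0.0 else 0.0

    for j in range(N):
        _rhs(y, Etab[2 * j], par, k1)
        for i in range(12):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        _rhs(yt, Etab[2 * j + 1], par, k2)
        for i in range(12):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        _rhs(yt, Etab[2 * j + 1], par, k3)
        for i in range(12):
            yt[i] = y[i] + dt * k3[i]
        _rhs(yt, Etab[2 * j + 2], par, k4)
        for i in range(12):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        for v in range(8, 12):
            if y[v] < 0.0:
                y[v] = 0.0

        av_open = y[8] > 0.0
        pv_open = y[9] > 0.0
        if av_open:
            lv_et += dt
            if not av_prev and np.isnan(pao_edp):
                pao_edp = y[4]
        if pv_open:
            rv_et += dt
            if not pv_prev and np.isnan(ppa_edp):
                ppa_edp = y[5]
        av_prev = av_open
        pv_prev = pv_open

        if y[4] > pao_max:
            pao_max = y[4]
        if y[5] > ppa_max:
            ppa_max = y[5]
        if y[0] > lv_max:
            lv_max = y[0]
        if y[0] < lv_min:
            lv_min = y[0]
        if y[1] > rv_max:
            rv_max = y[1]
        if y[1] < rv_min:
            rv_min = y[1]
        pao_sum += y[4]

        if record:
            for i in range(12):
                traj[j + 1, i] = y[i]
            openrec[j + 1, 0] = 1.0 if av_open else 0.0
            openrec[j + 1, 1] = 1.0 if pv_open else 0.0
            openrec[j + 1, 2] = 1.0 if y[10] > 0.0 else 0.0
            openrec[j + 1, 3] = 1.0 if y[11] > 0.0 else 0.0

    stats[0] = pao_max
    stats[1] = pao_edp
    stats[2] = lv_max
    stats[3] = lv_min
    stats[4] = lv_et
    stats[5] = ppa_max
    stats[6] = ppa_edp
    stats[7] = rv_max
    stats[8] = rv_min
    stats[9] = rv_et
    stats[10] = pao_sum / N
    stats[12] = _total_volume(y, par)


@njit(cache=True)
def _run_to_periodic(y, par, Etab, N, dt, max_cycles, tol, stats, traj, openrec):
    prev = y.copy()
    cycles = 0
    converged = False
    blown_up = False
    for _ in range(max_cycles):
        _one_cycle(y, par, Etab, N, dt, stats, traj, openrec, False)
        cycles += 1
        for i in range(12):
            if not np.isfinite(y[i]):
                blown_up = True
        if blown_up:
            break
        rel = 0.0
        for i in range(12):
            den = abs(prev[i])
            if den < 1.0:
                den = 1.0
            r = abs(y[i] - prev[i]) / den
            if r > rel:
                rel = r
        if rel < tol:
            converged = True
            break
        for i in range(12):
            prev[i] = y[i]
    return cycles, converged, blown_up


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


def _elastance_table(params: WBCParameters, N: int) -> np.ndarray:
    """E(t) for all chambers at the 2N+1 half-step times of one cycle."""
    t = np.arange(2 * N + 1) * (params.T / N / 2.0)
    tn = (t / params.T) % 1.0
    ta = (tn + ATRIAL_OFFSET_FRAC) % 1.0
    tab = np.empty((2 * N + 1, 4))
    tab[:, 0] = params.lv_emin + (params.lv_emax - params.lv_emin) * normalized_elastance(
        tn, params.lv_tau / params.T)
    tab[:, 1] = params.rv_emin + (params.rv_emax - params.rv_emin) * normalized_elastance(
        tn, params.rv_tau / params.T)
    tab[:, 2] = params.la_emin + (params.la_emax - params.la_emin) * normalized_elastance(
        ta, params.la_tau / params.T)
    tab[:, 3] = params.ra_emin + (params.ra_emax - params.ra_emin) * normalized_elastance(
        ta, params.ra_tau / params.T)
    return tab


def _initial_state(params: WBCParameters) -> np.ndarray:
    return np.array([
        params.lv_v0 + 90.0, params.rv_v0 + 90.0,
        params.la_v0 + 50.0, params.ra_v0 + 50.0,
        85.0, 15.0, 7.0, 9.0,
        0.0, 0.0, 0.0, 0.0,
    ])


@dataclass
class SimulationResult:
    """Final (periodic) cycle of a closed-loop run."""

    t: np.ndarray  # (N+1,) absolute time within the cycle
    volumes: np.ndarray  # (N+1, 4): LV, RV, LA, RA (mL)
    pressures: np.ndarray  # (N+1, 4): P_Ao, P_PA, P_sysVen, P_pulVen (mmHg)
    flows: np.ndarray  # (N+1, 4): aortic, pulmonary, mitral, tricuspid (mL/s)
    valve_open: np.ndarray  # (N+1, 4) booleans
    cycles: int
    converged: bool
    periodicity_tol: float
    dt: float
    params: WBCParameters
    volume_drift: float
    stats: np.ndarray = field(repr=False, default=None)


def simulate(params: WBCParameters, dt: float = 1e-4, max_cycles: int = 30,
             periodicity_tol: float = 1e-4) -> SimulationResult:
    """Run to periodic steady state and record the final cycle.

    Raises :class:`IntegrationError` on numerical blow-up; non-convergence
    within ``max_cycles`` is flagged on the result, not raised.
    """
    params.validate()
    N = max(2, int(round(params.T / dt)))
    dt_eff = params.T / N
    Etab = _elastance_table(params, N)
    par = _pack(params)
    y = _initial_state(params)
    stats = np.empty(13)
    dummy_traj = np.empty((1, 12))
    dummy_open = np.empty((1, 4))
    cycles, converged, blown_up = _run_to_periodic(
        y, par, Etab, N, dt_eff, max_cycles, periodicity_tol, stats, dummy_traj, dummy_open)
    if blown_up:
        raise IntegrationError(
            f"state became non-finite during cycle {cycles} (t ~ {cycles * params.T:.3f} s)")
    traj = np.empty((N + 1, 12))
    openrec = np.empty((N + 1, 4))
    _one_cycle(y, par, Etab, N, dt_eff, stats, traj, openrec, True)
    drift = abs(stats[12] - stats[11]) / stats[11]
    return SimulationResult(
        t=np.arange(N + 1) * dt_eff,
        volumes=traj[:, 0:4],
        pressures=traj[:, 4:8],
        flows=traj[:, 8:12],
        valve_open=openrec.astype(bool),
        cycles=cycles + 1,
        converged=converged,
        periodicity_tol=periodicity_tol,
        dt=dt_eff,
        params=params,
        volume_drift=float(drift),
        stats=stats.copy(),
    )


def extract_measurements(result: SimulationResult) -> MeasurementVector:
    """Read the clinical measurement vector off the final recorded cycle.

    Systolic pressures are cycle maxima of the arterial traces;
    end-diastolic pressures are the arterial pressures at the instant the
    ventricular outflow valve opens; EDV/ESV are the ventricular volume
    extrema; ejection time is the total time the outflow valve is open.
    """
    if not result.converged:
        raise DegeneratePhysiologyError("simulation did not reach periodic steady state")
    meas = {}
    for prefix, (p_col, v_col, valve_col) in {
        "sys": (0, 0, 0), "pul": (1, 1, 1),
    }.items():
        p = result.pressures[:, p_col]
        v = result.volumes[:, v_col]
        open_ = result.valve_open[:, valve_col]
        openings = np.nonzero(open_[1:] & ~open_[:-1])[0] + 1
        if open_.sum() == 0 or len(openings) == 0:
            raise DegeneratePhysiologyError("outflow valve never opened in the final cycle")
        edp = p[openings[0]]
        et = float(open_[1:].sum()) * result.dt
        if prefix == "sys":
            meas.update(p_ao_sys=p.max(), p_ao_edp=edp, lv_edv=v.max(), lv_esv=v.min(), lv_et=et)
        else:
            meas.update(p_pa_sys=p.max(), p_pa_edp=edp, rv_edv=v.max(), rv_esv=v.min(), rv_et=et)
    mv = MeasurementVector(**meas)
    mv.check(result.params.T)
    return mv


def simulate_measurements_batch(param_list, dt: float = 1e-4, max_cycles: int = 30,
                                periodicity_tol: float = 1e-4):
    """Vector of streamed measurement vectors for many parameter sets.

    Returns (measurements (n, 10), ok (n,) bool, info dict of diagnostics).
    A sample is not-ok when it blows up, fails to converge, never opens an
    outflow valve, violates the measurement sanity invariants, or drifts
    more than 0.5% in blood volume over the last cycle.
    """
    n = len(param_list)
    meas = np.full((n, 10), np.nan)
    ok = np.zeros(n, dtype=bool)
    cycles_used = np.zeros(n, dtype=int)
    drift = np.full(n, np.nan)
    stats = np.empty(13)
    dummy_traj = np.empty((1, 12))
    dummy_open = np.empty((1, 4))
    for i, params in enumerate(param_list):
        N = max(2, int(round(params.T / dt)))
        dt_eff = params.T / N
        Etab = _elastance_table(params, N)
        par = _pack(params)
        y = _initial_state(params)
        cycles, converged, blown_up = _run_to_periodic(
            y, par, Etab, N, dt_eff, max_cycles, periodicity_tol, stats,
            dummy_traj, dummy_open)
        cycles_used[i] = cycles
        if blown_up or not converged:
            continue
        m = stats[:10].copy()
        drift[i] = abs(stats[12] - stats[11]) / stats[11]
        if np.any(~np.isfinite(m)):
            continue  # a valve never opened
        good = (
            m[0] > m[1] and m[5] > m[6]
            and m[2] > m[3] and m[7] > m[8]
            and 0.0 < m[4] < params.T and 0.0 < m[9] < params.T
            and drift[i] < 0.005
        )
        if good:
            meas[i] = m
            ok[i] = True
    return meas, ok, {"cycles": cycles_used, "drift": drift}
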