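"""Closed-loop circulatory network with leaky valves and an LVAD flow source.

Eight volume compartments — LV, LA, RV, RA, systemic artery (SA), systemic
vein (SV), pulmonary artery (PA), pulmonary vein (PV) — are connected in the
loop ``RV -> PA -> PV -> LA -> LV -> SA -> SV -> RA -> RV``.  The four
valves are resistive diodes; the mitral and aortic valves optionally leak a
fixed percentage (the scale factor SF) of the forward-law flux when the
gradient reverses, which models mitral / aortic regurgitation.  A
continuous-flow LVAD is an ideal flow generator withdrawing blood from the
LA (LAAO topology) or the LV (LVAO topology) and injecting it into the
systemic artery.

State vector: the eight compartment volumes plus the attached cross-bridge
fraction of each ventricle.  Total blood volume is conserved exactly by
construction (every flow appears once as an outflow and once as an inflow).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .calcium import CaTransientParams, _ca_scalar, ca_transient
from .chambers import VentricleParams, compliance_pressure, ventricular_pressure
from .myofilament import MyofilamentParams, xb_rhs

__all__ = [
    "CircParams",
    "LvadConfig",
    "CirculationState",
    "ModelConfig",
    "SimulationResult",
    "mitral_flow",
    "aortic_flow",
    "lvad_flows",
    "network_rhs",
    "initial_state",
    "simulate",
]

logger = logging.getLogger(__name__)

STATE_FIELDS = (
    "v_lv", "v_la", "v_rv", "v_ra", "v_sa", "v_sv", "v_pa", "v_pv",
    "a_lv", "a_rv",
)

LVAD_MODES = ("none", "laao", "lvao")

# Fraction of the inlet chamber's unstressed volume below which pump flow is
# linearly derated to zero (suction guard).
SUCTION_GUARD_FRACTION = 0.1


@dataclass(frozen=True)
class CircParams:
    """Resistances (mmHg s/mL), compliances (mL/mmHg), unstressed volumes
    (mL) and valve leak scale factors (percent) of the vascular network.

    ``sf_mi`` / ``sf_ao`` set the mitral / aortic regurgitation severity:
    the backward flux is ``sf/100`` of the forward-law flux at the same
    pressure gradient (0 = competent valve).
    """

    r_mi: float = 0.04
    r_ao: float = 0.015
    r_tr: float = 0.03
    r_pu: float = 0.06
    r_sa: float = 3.4
    r_sv: float = 0.03
    r_pa: float = 0.10
    r_pv: float = 0.02
    c_la: float = 4.0
    c_ra: float = 8.0
    c_sa: float = 3.0
    c_sv: float = 40.0
    c_pa: float = 4.0
    c_pv: float = 8.0
    v0_la: float = 5.0
    v0_ra: float = 5.0
    v0_sa: float = 30.0
    v0_sv: float = 50.0
    v0_pa: float = 10.0
    v0_pv: float = 20.0
    sf_mi: float = 0.0
    sf_ao: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_mi", "r_ao", "r_tr", "r_pu", "r_sa", "r_sv", "r_pa",
                     "r_pv", "c_la", "c_ra", "c_sa", "c_sv", "c_pa", "c_pv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sf_mi", "sf_ao"):
            if not 0.0 <= getattr(self, name) <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100] percent")
        for name in ("v0_la", "v0_ra", "v0_sa", "v0_sv", "v0_pa", "v0_pv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class LvadConfig:
    """Cannulation topology and constant pump flux.

    ``mode`` is ``"none"`` (no pump), ``"laao"`` (LA -> aorta) or ``"lvao"``
    (LV -> aorta); ``flow`` is the constant volumetric rate in mL/s.
    """

    mode: str = "none"
    flow: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in LVAD_MODES:
            raise ValueError(f"unknown LVAD mode {self.mode!r}; expected one of {LVAD_MODES}")
        if self.flow < 0:
            raise ValueError("pump flow must be non-negative")
        if self.mode == "none" and self.flow != 0:
            raise ValueError("pump flow must be zero when mode is 'none'")


@dataclass
class CirculationState:
    """Compartment volumes (mL) and ventricular cross-bridge fractions."""

    v_lv: float
    v_la: float
    v_rv: float
    v_ra: float
    v_sa: float
    v_sv: float
    v_pa: float
    v_pv: float
    a_lv: float = 0.0
    a_rv: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_FIELDS[:8]:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("a_lv", "a_rv"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CirculationState":
        return cls(**dict(zip(STATE_FIELDS, map(float, y))))

    @property
    def total_volume(self) -> float:
        return sum(getattr(self, f) for f in STATE_FIELDS[:8])


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterization of one closed-loop simulation."""

    calcium: CaTransientParams = field(default_factory=CaTransientParams)
    myofilament: MyofilamentParams = field(default_factory=MyofilamentParams)
    lv: VentricleParams = field(default_factory=lambda: VentricleParams(
        v0=10.0, beta=0.15, kappa=0.028, passive_scale=5.0,
        sl_ref=1.7, v_ref=100.0, p_act_gain=2.5))
    rv: VentricleParams = field(default_factory=lambda: VentricleParams(
        v0=8.0, beta=0.12, kappa=0.04, passive_scale=5.0,
        sl_ref=2.1, v_ref=70.0, p_act_gain=0.45))
    circ: CircParams = field(default_factory=CircParams)
    lvad: LvadConfig = field(default_factory=LvadConfig)
    total_blood_volume: float = 1000.0

    def __post_init__(self) -> None:
        if self.total_blood_volume <= 0:
            raise ValueError("total_blood_volume must be positive")

    def with_(self, **kwargs) -> "ModelConfig":
        """Return a copy with the given top-level fields replaced."""
        return replace(self, **kwargs)


def mitral_flow(p_la: float, p_lv: float, r_mi: float, sf: float = 0.0) -> float:
    """Mitral valve flow (mL/s, positive LA -> LV) with optional leak.

    Forward (LA filling the LV) the valve is an ohmic resistor
    ``(p_la - p_lv) / r_mi``; with the gradient reversed (ventricular
    systole) a leaky valve passes ``sf`` percent of the forward-law flux,
    i.e. the backward branch has effective resistance ``r_mi * 100 / sf``.
    Both branches vanish at zero gradient, so the law is continuous.
    """
    if r_mi <= 0:
        raise ValueError("r_mi must be positive")
    if not 0.0 <= sf <= 100.0:
        raise ValueError("sf must lie in [0, 100] percent")
    dp = p_la - p_lv
    if dp > 0:
        return dp / r_mi
    return dp / r_mi * sf / 100.0


def aortic_flow(p_lv: float, p_ao: float, r_ao: float, sf: float = 0.0) -> float:
    """Aortic valve flow (mL/s, positive LV -> aorta); mirror of the mitral law."""
    if r_ao <= 0:
        raise ValueError("r_ao must be positive")
    if not 0.0 <= sf <= 100.0:
        raise ValueError("sf must lie in [0, 100] percent")
    dp = p_lv - p_ao
    if dp > 0:
        return dp / r_ao
    return dp / r_ao * sf / 100.0


def lvad_flows(config: LvadConfig) -> tuple[float, float, float]:
    """Nominal pump flows ``(withdraw_la, withdraw_lv, inject_sa)`` in mL/s.

    The pump conserves volume: injection always equals total withdrawal.
    """
    if config.mode == "none":
        return (0.0, 0.0, 0.0)
    if config.mode == "laao":
        return (config.flow, 0.0, config.flow)
    if config.mode == "lvao":
        return (0.0, config.flow, config.flow)
    raise ValueError(f"unknown LVAD mode {config.mode!r}")


def _suction_factor(v_inlet: float, v_unstressed: float) -> float:
    """Linear derating of pump flow as the inlet chamber approaches collapse.

    Full flow above ``SUCTION_GUARD_FRACTION`` of the unstressed volume,
    linearly reduced to zero as the chamber empties completely.
    """
    thresh = SUCTION_GUARD_FRACTION * v_unstressed
    if v_inlet >= thresh:
        return 1.0
    return max(0.0, v_inlet / thresh)


def network_rhs(t: float, state: CirculationState, cfg: ModelConfig) -> np.ndarray:
    """Time derivative of the full state, composed from the audited flow laws.

    Returns an array ordered as ``STATE_FIELDS`` (volume rates in mL/s,
    cross-bridge rates in 1/s).  The eight volume derivatives sum to zero
    identically: the loop is closed and the pump's withdrawal equals its
    injection.
    """
    y = state.as_array() if isinstance(state, CirculationState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state at t={t}: {y}")
    if np.any(y[:8] <= 0):
        bad = [f for f, v in zip(STATE_FIELDS[:8], y[:8]) if v <= 0]
        raise ValueError(f"non-positive compartment volume(s) {bad} at t={t}")

    c = cfg.circ
    v_lv, v_la, v_rv, v_ra, v_sa, v_sv, v_pa, v_pv, a_lv, a_rv = y

    p_lv = ventricular_pressure(v_lv, a_lv, cfg.lv, cfg.myofilament)
    p_rv = ventricular_pressure(v_rv, a_rv, cfg.rv, cfg.myofilament)
    p_la = compliance_pressure(v_la, c.c_la, c.v0_la)
    p_ra = compliance_pressure(v_ra, c.c_ra, c.v0_ra)
    p_sa = compliance_pressure(v_sa, c.c_sa, c.v0_sa)
    p_sv = compliance_pressure(v_sv, c.c_sv, c.v0_sv)
    p_pa = compliance_pressure(v_pa, c.c_pa, c.v0_pa)
    p_pv = compliance_pressure(v_pv, c.c_pv, c.v0_pv)

    q_mi = mitral_flow(p_la, p_lv, c.r_mi, c.sf_mi)
    q_ao = aortic_flow(p_lv, p_sa, c.r_ao, c.sf_ao)
    q_tr = mitral_flow(p_ra, p_rv, c.r_tr, 0.0)   # competent tricuspid diode
    q_pu = aortic_flow(p_rv, p_pa, c.r_pu, 0.0)   # competent pulmonary diode
    q_sa = (p_sa - p_sv) / c.r_sa
    q_sv = (p_sv - p_ra) / c.r_sv
    q_pa = (p_pa - p_pv) / c.r_pa
    q_pv = (p_pv - p_la) / c.r_pv

    w_la, w_lv, inject = lvad_flows(cfg.lvad)
    if cfg.lvad.mode == "laao":
        f = _suction_factor(v_la, c.v0_la)
        w_la, inject = w_la * f, inject * f
    elif cfg.lvad.mode == "lvao":
        f = _suction_factor(v_lv, cfg.lv.v0)
        w_lv, inject = w_lv * f, inject * f

    ca = _ca_scalar(t * 1000.0, cfg.calcium)

    return np.array([
        q_mi - q_ao - w_lv,            # v_lv
        q_pv - q_mi - w_la,            # v_la
        q_tr - q_pu,                   # v_rv
        q_sv - q_tr,                   # v_ra
        q_ao + inject - q_sa,          # v_sa
        q_sa - q_sv,                   # v_sv
        q_pu - q_pa,                   # v_pa
        q_pa - q_pv,                   # v_pv
        xb_rhs(a_lv, ca, cfg.myofilament),
        xb_rhs(a_rv, ca, cfg.myofilament),
    ])


def _make_rhs(cfg: ModelConfig):
    """Build a fast scalar closure equivalent to :func:`network_rhs`.

    All parameters are hoisted into locals; the piecewise laws are inlined
    with ``math`` calls.  A unit test asserts agreement with the composed
    public operations.
    """
    c = cfg.circ
    lv, rv, mp, cap = cfg.lv, cfg.rv, cfg.myofilament, cfg.calcium
    lvad_mode, lvad_flow = cfg.lvad.mode, cfg.lvad.flow
    exp = math.exp
    third = 1.0 / 3.0
    # myofilament constants
    f_app, g_xb, ca50, hh = mp.f_app, mp.g_xb, mp.ca50, mp.hill_h
    lt2, lb2, ltn, span = mp.len_thick / 2.0, mp.len_hbare / 2.0, mp.len_thin, mp.len_thick - mp.len_hbare
    t_max = mp.t_max
    ca_norm, tr, td, bcl = cap._norm, cap.tau_rise, cap.tau_decay, cap.bcl
    ca_dia = cap.ca_diastolic
    ca_amp = cap.ca_amplitude * cap.hf_amplitude_factor
    sf_mi, sf_ao = c.sf_mi / 100.0, c.sf_ao / 100.0
    guard_la = SUCTION_GUARD_FRACTION * c.v0_la
    guard_lv = SUCTION_GUARD_FRACTION * lv.v0

    def p_vent(v, a, vp):
        dv = v - vp.v0
        if dv >= 0:
            p = vp.beta * (exp(vp.kappa * dv) - 1.0)
        else:
            p = vp.beta * vp.kappa * dv
        p *= vp.passive_scale
        if a > 0.0:
            sl = vp.sl_ref * (v / vp.v_ref) ** third
            ze = lt2 if lt2 < 0.5 * sl else 0.5 * sl
            cle = ltn - 0.5 * sl
            if cle < lb2:
                cle = lb2
            sovf = 2.0 * (ze - cle) / span
            if sovf < 0.0:
                sovf = 0.0
            elif sovf > 1.0:
                sovf = 1.0
            p += vp.p_act_gain * t_max * a * sovf * (vp.v_ref / v) ** third
        return p

    def rhs(t, y):
        v_lv, v_la, v_rv, v_ra, v_sa, v_sv, v_pa, v_pv, a_lv, a_rv = y

        p_lv = p_vent(v_lv, a_lv, lv)
        p_rv = p_vent(v_rv, a_rv, rv)
        p_la = (v_la - c.v0_la) / c.c_la
        p_la = p_la if p_la > 0.0 else 0.0
        p_ra = (v_ra - c.v0_ra) / c.c_ra
        p_ra = p_ra if p_ra > 0.0 else 0.0
        p_sa = (v_sa - c.v0_sa) / c.c_sa
        p_sa = p_sa if p_sa > 0.0 else 0.0
        p_sv = (v_sv - c.v0_sv) / c.c_sv
        p_sv = p_sv if p_sv > 0.0 else 0.0
        p_pa = (v_pa - c.v0_pa) / c.c_pa
        p_pa = p_pa if p_pa > 0.0 else 0.0
        p_pv = (v_pv - c.v0_pv) / c.c_pv
        p_pv = p_pv if p_pv > 0.0 else 0.0

        dp = p_la - p_lv
        q_mi = dp / c.r_mi if dp > 0.0 else dp / c.r_mi * sf_mi
        dp = p_lv - p_sa
        q_ao = dp / c.r_ao if dp > 0.0 else dp / c.r_ao * sf_ao
        dp = p_ra - p_rv
        q_tr = dp / c.r_tr if dp > 0.0 else 0.0
        dp = p_rv - p_pa
        q_pu = dp / c.r_pu if dp > 0.0 else 0.0
        q_sa = (p_sa - p_sv) / c.r_sa
        q_sv = (p_sv - p_ra) / c.r_sv
        q_pa = (p_pa - p_pv) / c.r_pa
        q_pv = (p_pv - p_la) / c.r_pv

        w_la = w_lv = inject = 0.0
        if lvad_mode == "laao":
            f = 1.0 if v_la >= guard_la else (v_la / guard_la if v_la > 0.0 else 0.0)
            w_la = inject = lvad_flow * f
        elif lvad_mode == "lvao":
            f = 1.0 if v_lv >= guard_lv else (v_lv / guard_lv if v_lv > 0.0 else 0.0)
            w_lv = inject = lvad_flow * f

        s = (t * 1000.0) % bcl
        ca = ca_dia + ca_amp * ca_norm * (1.0 - exp(-s / tr)) * exp(-s / td)
        x = (ca / ca50) ** hh
        hill = x / (1.0 + x)

        return (
            q_mi - q_ao - w_lv,
            q_pv - q_mi - w_la,
            q_tr - q_pu,
            q_sv - q_tr,
            q_ao + inject - q_sa,
            q_sa - q_sv,
            q_pu - q_pa,
            q_pa - q_pv,
            f_app * hill * (1.0 - a_lv) - g_xb * a_lv,
            f_app * hill * (1.0 - a_rv) - g_xb * a_rv,
        )

    return rhs


# Default distribution of the non-venous initial volumes (mL); the systemic
# venous compartment absorbs the remainder of the total blood volume, which
# makes total volume the natural preload knob for calibration.
_INITIAL_VOLUMES = {
    "v_lv": 100.0,
    "v_la": 40.0,
    "v_rv": 60.0,
    "v_ra": 15.0,
    "v_sa": 330.0,
    "v_pa": 35.0,
    "v_pv": 80.0,
}


def initial_state(cfg: ModelConfig) -> CirculationState:
    """Default initial condition with the configured total blood volume."""
    v_sv = cfg.total_blood_volume - sum(_INITIAL_VOLUMES.values())
    if v_sv <= 0:
        raise ValueError(
            f"total_blood_volume={cfg.total_blood_volume} too small for the "
            f"default compartment distribution")
    return CirculationState(v_sv=v_sv, a_lv=0.02, a_rv=0.02, **_INITIAL_VOLUMES)


@dataclass
class SimulationResult:
    """Dense 1 kHz output of one run plus run-level diagnostics.

    ``data`` holds the resampled time series (volumes, cross-bridge
    fractions, pressures, flows, pump flows, calcium, ATP rates);
    ``periodicity_defect`` is the relative sup-norm difference of the LV
    volume and pressure between the last two complete cycles (a steady-state
    check); ``suction_active`` flags any pump derating during the run.
    """

    data: pd.DataFrame
    config: ModelConfig
    periodicity_defect: float
    suction_active: bool
    solver_stats: dict

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")


def _vec_sovf(sl: np.ndarray, mp: MyofilamentParams) -> np.ndarray:
    ze = np.minimum(mp.len_thick / 2.0, sl / 2.0)
    cle = np.maximum(mp.len_thin - sl / 2.0, mp.len_hbare / 2.0)
    return np.clip(2.0 * (ze - cle) / (mp.len_thick - mp.len_hbare), 0.0, 1.0)


def _vec_ventricular_pressure(v, a, vp: VentricleParams, mp: MyofilamentParams):
    dv = v - vp.v0
    p_pas = vp.passive_scale * np.where(
        dv >= 0, vp.beta * (np.exp(vp.kappa * np.maximum(dv, 0.0)) - 1.0),
        vp.beta * vp.kappa * dv)
    sl = vp.sl_ref * (v / vp.v_ref) ** (1.0 / 3.0)
    t_act = mp.t_max * a * _vec_sovf(sl, mp)
    return p_pas + vp.p_act_gain * t_act * (vp.v_ref / v) ** (1.0 / 3.0), sl


def _postprocess(t: np.ndarray, y: np.ndarray, cfg: ModelConfig) -> pd.DataFrame:
    """Recompute pressures, flows and ATP rates on the dense output grid."""
    c = cfg.circ
    mp = cfg.myofilament
    cols = {"time_s": t}
    for i, name in enumerate(STATE_FIELDS):
        cols[name] = y[i]

    p_lv, sl_lv = _vec_ventricular_pressure(y[0], y[8], cfg.lv, mp)
    p_rv, sl_rv = _vec_ventricular_pressure(y[2], y[9], cfg.rv, mp)
    p_la = np.maximum(0.0, (y[1] - c.v0_la) / c.c_la)
    p_ra = np.maximum(0.0, (y[3] - c.v0_ra) / c.c_ra)
    p_sa = np.maximum(0.0, (y[4] - c.v0_sa) / c.c_sa)
    p_sv = np.maximum(0.0, (y[5] - c.v0_sv) / c.c_sv)
    p_pa = np.maximum(0.0, (y[6] - c.v0_pa) / c.c_pa)
    p_pv = np.maximum(0.0, (y[7] - c.v0_pv) / c.c_pv)

    dp_mi = p_la - p_lv
    q_mi = np.where(dp_mi > 0, dp_mi / c.r_mi, dp_mi / c.r_mi * c.sf_mi / 100.0)
    dp_ao = p_lv - p_sa
    q_ao = np.where(dp_ao > 0, dp_ao / c.r_ao, dp_ao / c.r_ao * c.sf_ao / 100.0)
    q_tr = np.maximum(0.0, (p_ra - p_rv) / c.r_tr)
    q_pu = np.maximum(0.0, (p_rv - p_pa) / c.r_pu)

    w_la = np.zeros_like(t)
    w_lv = np.zeros_like(t)
    inject = np.zeros_like(t)
    if cfg.lvad.mode == "laao":
        f = np.clip(y[1] / (SUCTION_GUARD_FRACTION * c.v0_la), 0.0, 1.0)
        w_la = inject = cfg.lvad.flow * f
    elif cfg.lvad.mode == "lvao":
        f = np.clip(y[0] / (SUCTION_GUARD_FRACTION * cfg.lv.v0), 0.0, 1.0)
        w_lv = inject = cfg.lvad.flow * f

    ca = ca_transient(t * 1000.0, cfg.calcium)

    cols.update(
        p_lv=p_lv, p_la=p_la, p_rv=p_rv, p_ra=p_ra, p_sa=p_sa, p_sv=p_sv,
        p_pa=p_pa, p_pv=p_pv,
        q_mi=q_mi, q_ao=q_ao, q_tr=q_tr, q_pu=q_pu,
        q_sa=(p_sa - p_sv) / c.r_sa, q_sv=(p_sv - p_ra) / c.r_sv,
        q_pa=(p_pa - p_pv) / c.r_pa, q_pv=(p_pv - p_la) / c.r_pv,
        q_pump_la=w_la, q_pump_lv=w_lv, q_pump_out=inject,
        ca_uM=ca, sl_lv=sl_lv,
        atp_lv=mp.g_xb * y[8] * _vec_sovf(sl_lv, mp),
        atp_rv=mp.g_xb * y[9] * _vec_sovf(sl_rv, mp),
    )
    return pd.DataFrame(cols)


def _periodicity_defect(df: pd.DataFrame, bcl_s: float) -> float:
    """Relative sup-norm change of v_lv and p_lv between the last two cycles."""
    t = df["time_s"].to_numpy()
    dt = t[1] - t[0]
    n = int(round(bcl_s / dt))
    if len(t) < 2 * n + 1:
        return math.nan
    worst = 0.0
    for col in ("v_lv", "p_lv"):
        x = df[col].to_numpy()
        last = x[-n:]
        prev = x[-2 * n:-n]
        scale = max(np.max(np.abs(last)), 1e-12)
        worst = max(worst, float(np.max(np.abs(last - prev)) / scale))
    return worst


def simulate(
    cfg: ModelConfig,
    duration: float = 20.0,
    initial: Optional[CirculationState] = None,
    dt_out: float = 1e-3,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-8,
    max_step: float = 5e-3,
) -> SimulationResult:
    """Integrate the closed loop for ``duration`` seconds.

    Uses a stiff-capable adaptive solver (the diode valves make the
    right-hand side only piecewise smooth) and resamples the dense output on
    a fixed ``dt_out`` grid, so identical configurations yield identical
    output tables.  Raises ``RuntimeError`` (carrying the last valid time)
    if the solver fails.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    state0 = initial if initial is not None else initial_state(cfg)
    y0 = state0.as_array()
    t_eval = np.arange(0.0, duration + dt_out / 2.0, dt_out)
    rhs = _make_rhs(cfg)
    sol = solve_ivp(
        rhs, (0.0, duration), y0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(
            f"ODE solver failed at t={t_last:.4f}s: {sol.message}")

    df = _postprocess(sol.t, sol.y, cfg)
    defect = _periodicity_defect(df, cfg.calcium.bcl / 1000.0)

    suction = False
    if cfg.lvad.mode == "laao":
        suction = bool(df["v_la"].min() < SUCTION_GUARD_FRACTION * cfg.circ.v0_la)
    elif cfg.lvad.mode == "lvao":
        suction = bool(df["v_lv"].min() < SUCTION_GUARD_FRACTION * cfg.lv.v0)
    if suction:
        logger.warning("suction guard active: pump flow was derated (mode=%s)",
                       cfg.lvad.mode)

    stats = {"nfev": int(sol.nfev), "njev": int(getattr(sol, "njev", 0) or 0),
             "method": method, "rtol": rtol, "atol": atol}
    return SimulationResult(df, cfg, defect, suction, stats)
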