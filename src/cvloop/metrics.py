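"""Steady-state cycle extraction and the per-cycle hemodynamic metric panel.

A run is summarized on one steady-state beat (by default the cycle from
18.6 s to 19.2 s of a 20 s simulation): peak left-atrial and left-ventricular
pressures (LAPP, LVPP), aortic pressures, end-diastolic / end-systolic
volumes, stroke volume and ejection fraction, PV-loop stroke work, the mean
myofilament ATP consumption rate, and per-valve regurgitant fractions.
"Aortic pressure" is the systemic-artery compartment pressure — the network
has no separate aortic chamber.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CycleMetrics",
    "extract_cycle",
    "stroke_work",
    "ejection_fraction",
    "cycle_metrics",
]

DEFAULT_WINDOW_START = 18.6   # s; steady-state cycle of a 20 s run


@dataclass(frozen=True)
class CycleMetrics:
    """Scalar panel of one steady-state cardiac cycle.

    ``ef`` is volume-based, (EDV - ESV) / EDV; ``ef_forward`` counts only
    blood actually ejected forward through the aortic valve (the two agree
    for a competent valve but differ under regurgitation or an LVAD).
    ``lv_minus_ao_max`` is the cycle maximum of P_LV - P_AO: negative means
    the aortic valve never opened (isovolumic contraction).
    """

    lapp: float
    lvpp: float
    ao_peak: float
    ao_mean: float
    edv: float
    esv: float
    sv: float
    ef: float
    stroke_work: float
    atp_mean: float
    regurgitant_fraction_mi: float
    regurgitant_fraction_ao: float
    ao_forward_volume: float
    ef_forward: float
    lv_minus_ao_max: float
    pump_flow_mean: float

    def __post_init__(self) -> None:
        if self.esv > self.edv + 1e-9:
            raise ValueError("esv must not exceed edv")
        if not -1e-9 <= self.ef <= 1.0 + 1e-9:
            raise ValueError("ef must lie in [0, 1]")
        if self.stroke_work < -1e-9:
            raise ValueError("stroke_work must be non-negative")
        if self.atp_mean < 0:
            raise ValueError("atp_mean must be non-negative")

    def as_dict(self) -> dict:
        return asdict(self)


def extract_cycle(series: pd.DataFrame, window_start: float = DEFAULT_WINDOW_START,
                  bcl_ms: float = 600.0) -> pd.DataFrame:
    """Slice exactly one cycle ``[window_start, window_start + bcl)`` (s).

    The defaults pick the 18.6--19.2 s steady-state beat of a 20 s run.
    Raises ``ValueError`` if the requested window is not fully covered.
    """
    t = series["time_s"].to_numpy()
    t_end = window_start + bcl_ms / 1000.0
    dt = t[1] - t[0]
    if window_start < t[0] - 1e-9 or t_end > t[-1] + dt / 2 + 1e-9:
        raise ValueError(
            f"window [{window_start}, {t_end}] s not covered by series "
            f"[{t[0]}, {t[-1]}] s")
    mask = (t >= window_start - 1e-9) & (t < t_end - 1e-9)
    return series.loc[mask].reset_index(drop=True)


def stroke_work(p, v) -> float:
    """Area enclosed by the PV loop (mmHg mL), via the shoelace formula.

    Orientation-corrected (absolute value), invariant to cyclic rotation of
    the samples, and zero for a degenerate (e.g. isovolumic) trajectory.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    if p.shape != v.shape:
        raise ValueError(f"pressure and volume series differ in length: {p.shape} vs {v.shape}")
    if p.size < 3:
        raise ValueError("need at least 3 samples to define a loop")
    area = 0.5 * np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p)
    return float(abs(area))


def ejection_fraction(edv: float, esv: float) -> float:
    """EF = (EDV - ESV) / EDV, a fraction in [0, 1]."""
    if edv <= 0:
        raise ValueError("edv must be positive")
    if esv < 0 or esv > edv:
        raise ValueError("require 0 <= esv <= edv")
    return (edv - esv) / edv


def _pos_neg_volumes(t: np.ndarray, q: np.ndarray) -> tuple[float, float]:
    """Trapezoid integrals of the positive and negative parts of a flow."""
    fwd = float(np.trapezoid(np.maximum(q, 0.0), t))
    bwd = float(np.trapezoid(np.maximum(-q, 0.0), t))
    return fwd, bwd


def cycle_metrics(cycle: pd.DataFrame) -> CycleMetrics:
    """Compute the scalar metric panel from one extracted cycle.

    LAPP / LVPP are whole-cycle pressure maxima; the mean ATP rate is the
    time average of the LV detachment-flux rate; regurgitant fractions are
    backward over forward valve volume per cycle (0 when nothing flows
    forward and nothing leaks).
    """
    if len(cycle) == 0:
        raise ValueError("empty cycle series")
    t = cycle["time_s"].to_numpy()
    p_lv = cycle["p_lv"].to_numpy()
    p_la = cycle["p_la"].to_numpy()
    p_sa = cycle["p_sa"].to_numpy()
    v_lv = cycle["v_lv"].to_numpy()
    atp = cycle["atp_lv"].to_numpy()

    edv = float(v_lv.max())
    esv = float(v_lv.min())
    sv = edv - esv
    span = t[-1] - t[0]
    mean = lambda x: float(np.trapezoid(x, t) / span) if span > 0 else float(x[0])

    mi_fwd, mi_bwd = _pos_neg_volumes(t, cycle["q_mi"].to_numpy())
    ao_fwd, ao_bwd = _pos_neg_volumes(t, cycle["q_ao"].to_numpy())
    rf_mi = mi_bwd / mi_fwd if mi_fwd > 0 else 0.0
    rf_ao = ao_bwd / ao_fwd if ao_fwd > 0 else 0.0

    return CycleMetrics(
        lapp=float(p_la.max()),
        lvpp=float(p_lv.max()),
        ao_peak=float(p_sa.max()),
        ao_mean=mean(p_sa),
        edv=edv,
        esv=esv,
        sv=sv,
        ef=ejection_fraction(edv, esv),
        stroke_work=stroke_work(p_lv, v_lv),
        atp_mean=mean(atp),
        regurgitant_fraction_mi=rf_mi,
        regurgitant_fraction_ao=rf_ao,
        ao_forward_volume=ao_fwd,
        ef_forward=ao_fwd / edv,
        lv_minus_ao_max=float(np.max(p_lv - p_sa)),
        pump_flow_mean=mean(cycle["q_pump_out"].to_numpy()),
    )
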