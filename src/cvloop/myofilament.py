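"""Reduced two-state cross-bridge model: active tension and ATP turnover.

A single ordinary differential equation tracks the attached cross-bridge
fraction ``a``::

    da/dt = f_app * H(Ca) * (1 - a) - g_xb * a,
    H(Ca) = Ca^h / (Ca^h + Ca50^h)

Attachment is gated by a Hill function of calcium; detachment is first order
with rate constant ``g_xb``.  Each detachment hydrolyses one ATP, so the ATP
consumption rate per unit volume is the detachment flux weighted by the
single-overlap fraction of thick filaments::

    E = (g_xb * a) * SOVF_thick(SL)

``SOVF_thick`` is the classic piecewise-linear single-overlap fraction of
sarcomere length built from the thick-filament length, the central bare zone
and the thin-filament length.  Active tension is
``T = t_max * a * SOVF_thick(SL)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MyofilamentParams",
    "CrossBridgeState",
    "sovf_thick",
    "xb_rhs",
    "xb_steady_state",
    "active_tension",
    "atp_rate",
]


@dataclass(frozen=True)
class MyofilamentParams:
    """Rate constants, calcium sensitivity and filament geometry.

    ``f_app`` / ``g_xb`` are the cross-bridge attachment / detachment rate
    constants (s^-1); ``ca50`` (uM) and ``hill_h`` set the calcium gate;
    ``t_max`` is the tension produced at full attachment and full overlap,
    on the mmHg-equivalent scale used by the chamber coupling.  Filament
    lengths are in um: ``len_thick`` (myosin), ``len_hbare`` (bare zone at
    its center) and ``len_thin`` (actin).
    """

    f_app: float = 80.0
    g_xb: float = 20.0
    ca50: float = 0.4
    hill_h: float = 6.0
    t_max: float = 140.0
    len_thick: float = 1.65
    len_hbare: float = 0.1
    len_thin: float = 1.2

    def __post_init__(self) -> None:
        for name in ("f_app", "g_xb", "ca50", "t_max", "len_thin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hill_h < 1:
            raise ValueError("hill_h must be >= 1")
        if not 0 < self.len_hbare < self.len_thick:
            raise ValueError("require 0 < len_hbare < len_thick")


@dataclass
class CrossBridgeState:
    """Attached cross-bridge fraction, a dimensionless number in [0, 1]."""

    a: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"attached fraction must lie in [0, 1], got {self.a}")


def _a_of(state) -> float:
    return state.a if isinstance(state, CrossBridgeState) else float(state)


def sovf_thick(sl: float, params: MyofilamentParams) -> float:
    """Single-overlap fraction of thick filaments at sarcomere length ``sl`` (um).

    Piecewise linear: the overlap region runs from the end of the thick
    filament (capped at half the sarcomere) back to the edge of the bare zone
    (or the thin-filament tip when the sarcomere is long), normalized by the
    crown-bearing half-length ``(len_thick - len_hbare) / 2`` per half
    sarcomere, and clamped to [0, 1].
    """
    if sl <= 0:
        raise ValueError(f"sarcomere length must be positive, got {sl}")
    sovr_ze = min(params.len_thick / 2.0, sl / 2.0)
    sovr_cle = max(params.len_thin - sl / 2.0, params.len_hbare / 2.0)
    frac = 2.0 * (sovr_ze - sovr_cle) / (params.len_thick - params.len_hbare)
    return min(1.0, max(0.0, frac))


def _hill(ca: float, params: MyofilamentParams) -> float:
    if ca <= 0.0:
        return 0.0
    x = (ca / params.ca50) ** params.hill_h
    return x / (1.0 + x)


def xb_rhs(state, ca: float, params: MyofilamentParams) -> float:
    """Rate of change of the attached fraction (s^-1) at calcium ``ca`` (uM).

    The vector field points inward at both bounds of [0, 1], so any
    trajectory started inside stays inside for every non-negative drive.
    """
    if ca < 0:
        raise ValueError("calcium concentration must be non-negative")
    a = _a_of(state)
    return params.f_app * _hill(ca, params) * (1.0 - a) - params.g_xb * a


def xb_steady_state(ca: float, params: MyofilamentParams) -> float:
    """Fixed point of the attachment ODE under constant calcium."""
    fh = params.f_app * _hill(ca, params)
    return fh / (fh + params.g_xb)


def active_tension(state, sl: float, params: MyofilamentParams) -> float:
    """Active tension ``t_max * a * SOVF_thick(sl)``, in t_max units."""
    return params.t_max * _a_of(state) * sovf_thick(sl, params)


def atp_rate(state, sl: float, params: MyofilamentParams) -> float:
    """ATP consumption rate E (s^-1): detachment flux times overlap fraction.

    The total detachment rate is ``g_xb * a`` (rate constant times occupied
    fraction); only cross-bridges within the single-overlap region cycle, so
    ``E = g_xb * a * SOVF_thick(sl)``.  E is zero exactly when no bridge is
    attached or there is no overlap.
    """
    return params.g_xb * _a_of(state) * sovf_thick(sl, params)
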