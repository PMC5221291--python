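"""0D pressure--volume laws for the cardiac chambers and vessels.

Each ventricle combines an exponential end-diastolic pressure--volume
relation (the passive stiffness curve, scaled by ``passive_scale`` to model
heart-failure remodeling) with an active component driven by the myofilament
model.  Sarcomere length follows chamber volume by cube-root scaling of a
quasi-spherical cavity, and the active pressure carries a Laplace-like
``(v_ref / v)^(1/3)`` attenuation with dilation.  Atria and vessels are
passive linear compliances floored at zero transmural pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .myofilament import MyofilamentParams, _a_of, active_tension

__all__ = [
    "VentricleParams",
    "passive_pressure",
    "sl_from_volume",
    "ventricular_pressure",
    "compliance_pressure",
]


@dataclass(frozen=True)
class VentricleParams:
    """Chamber-level parameters of one ventricle.

    ``v0`` (mL) is the unstressed volume where passive pressure vanishes;
    ``beta`` (mmHg) and ``kappa`` (1/mL) set the scale and steepness of the
    exponential passive curve; ``passive_scale`` multiplies the whole passive
    curve (5x models the stiffened failing myocardium, 1 is healthy);
    ``sl_ref`` (um) is the sarcomere length at the reference volume ``v_ref``
    (mL); ``p_act_gain`` converts myofilament tension into cavity pressure.
    """

    v0: float
    beta: float
    kappa: float
    passive_scale: float = 1.0
    sl_ref: float = 2.1
    v_ref: float = 100.0
    p_act_gain: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v0", "beta", "kappa", "sl_ref", "v_ref", "p_act_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.passive_scale < 1:
            raise ValueError("passive_scale must be >= 1")


def passive_pressure(v: float, params: VentricleParams) -> float:
    """Passive (relaxed) ventricular pressure at volume ``v`` (mL), mmHg.

    Exponential above the unstressed volume,
    ``passive_scale * beta * (exp(kappa (v - v0)) - 1)``, continued linearly
    (with the matching slope at ``v0``) below it so the law is C1 and
    strictly increasing everywhere.
    """
    if v <= 0:
        raise ValueError(f"volume must be positive, got {v}")
    dv = v - params.v0
    if dv >= 0:
        p = params.beta * (math.exp(params.kappa * dv) - 1.0)
    else:
        p = params.beta * params.kappa * dv
    return params.passive_scale * p


def sl_from_volume(v: float, params: VentricleParams) -> float:
    """Sarcomere length (um) at cavity volume ``v``: sl_ref (v/v_ref)^(1/3)."""
    if v <= 0:
        raise ValueError(f"volume must be positive, got {v}")
    return params.sl_ref * (v / params.v_ref) ** (1.0 / 3.0)


def ventricular_pressure(
    v: float,
    xb,
    vp: VentricleParams,
    mp: MyofilamentParams,
) -> float:
    """Total ventricular pressure: passive EDPVR plus myofilament-driven part.

    ``P = P_pas(v) + p_act_gain * T_act(a, sl(v)) * (v_ref / v)^(1/3)``.
    The cube-root factor mimics the Laplace-law loss of pressure-generating
    ability as the cavity dilates.  With no attached cross-bridges the
    pressure reduces exactly to the passive curve.
    """
    p_pas = passive_pressure(v, vp)
    a = _a_of(xb)
    if a == 0.0:
        return p_pas
    sl = sl_from_volume(v, vp)
    t_act = active_tension(a, sl, mp)
    return p_pas + vp.p_act_gain * t_act * (vp.v_ref / v) ** (1.0 / 3.0)


def compliance_pressure(v: float, c: float, v_unstressed: float) -> float:
    """Linear compliance pressure ``(v - v_unstressed) / c``, floored at 0 mmHg.

    The floor models venous/atrial collapse: a compartment below its
    unstressed volume exerts no positive transmural pressure.
    """
    if c <= 0:
        raise ValueError(f"compliance must be positive, got {c}")
    return max(0.0, (v - v_unstressed) / c)
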