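"""Periodic intracellular Ca2+ transient driving ventricular contraction.

The contraction drive is a paced (BCL-periodic) calcium transient with a
normalized rise--decay pulse shape.  Heart-failure remodeling is expressed as
a pure amplitude reduction: with ``hf_amplitude_factor = 0.3`` the peak
systolic rise above the diastolic level is 30% of normal (a 70% reduction),
with unchanged timing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["CaTransientParams", "ca_transient"]


@dataclass(frozen=True)
class CaTransientParams:
    """Shape parameters of the paced intracellular Ca2+ transient.

    Parameters
    ----------
    bcl:
        Basic cycle length (pacing period), ms.
    ca_diastolic:
        Resting (diastolic) Ca2+ concentration, uM.
    ca_amplitude:
        Normal peak-minus-diastolic amplitude, uM.
    tau_rise, tau_decay:
        Time constants of the upstroke and decay of the pulse, ms.
        ``tau_rise < tau_decay`` so the pulse rises faster than it decays.
    hf_amplitude_factor:
        Fraction of the normal amplitude retained; 1.0 is a healthy cell,
        0.3 models the failing cell (70% amplitude loss).
    """

    bcl: float = 600.0
    ca_diastolic: float = 0.1
    ca_amplitude: float = 1.0
    tau_rise: float = 20.0
    tau_decay: float = 150.0
    hf_amplitude_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.bcl <= 0:
            raise ValueError(f"bcl must be positive, got {self.bcl}")
        if self.ca_diastolic < 0:
            raise ValueError("ca_diastolic must be non-negative")
        if self.ca_amplitude <= 0:
            raise ValueError("ca_amplitude must be positive")
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError(
                "require 0 < tau_rise < tau_decay, got "
                f"tau_rise={self.tau_rise}, tau_decay={self.tau_decay}"
            )
        if not 0.0 <= self.hf_amplitude_factor <= 1.0:
            raise ValueError("hf_amplitude_factor must lie in [0, 1]")

    @cached_property
    def peak_time(self) -> float:
        """Time (ms after stimulus) at which the unnormalized pulse peaks.

        For w(s) = (1 - exp(-s/tr)) exp(-s/td) the stationary point solves
        exp(-s/tr) (1 + td/tr) = 1, i.e. s* = tr * log(1 + td/tr).
        """
        return self.tau_rise * math.log(1.0 + self.tau_decay / self.tau_rise)

    @cached_property
    def _norm(self) -> float:
        """Normalization constant making the pulse peak exactly 1."""
        s = self.peak_time
        w = (1.0 - math.exp(-s / self.tau_rise)) * math.exp(-s / self.tau_decay)
        return 1.0 / w


def ca_transient(t, params: CaTransientParams):
    """Intracellular Ca2+ concentration (uM) at time ``t`` (ms).

    The waveform is ``ca_diastolic + a_eff * w(t mod bcl)`` where ``w`` is a
    rise--decay pulse normalized to unit peak and
    ``a_eff = ca_amplitude * hf_amplitude_factor``.  It is exactly
    BCL-periodic and never falls below the diastolic level.

    Accepts a scalar or ndarray ``t``; negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    s = np.mod(t, params.bcl)
    w = params._norm * (1.0 - np.exp(-s / params.tau_rise)) * np.exp(-s / params.tau_decay)
    a_eff = params.ca_amplitude * params.hf_amplitude_factor
    out = params.ca_diastolic + a_eff * w
    return out if out.ndim else float(out)


def _ca_scalar(t_ms: float, p: CaTransientParams) -> float:
    """Fast scalar evaluation used inside the ODE right-hand side."""
    s = t_ms % p.bcl
    w = p._norm * (1.0 - math.exp(-s / p.tau_rise)) * math.exp(-s / p.tau_decay)
    return p.ca_diastolic + p.ca_amplitude * p.hf_amplitude_factor * w
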