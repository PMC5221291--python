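"""Configuration fixtures and YAML round-tripping.

``baseline_config()`` is the failing-heart fixture: heart-failure remodeling
is encoded by a 5x passive stiffness scale on both ventricles and a calcium
transient reduced to 30% of the normal amplitude, paced at a basic cycle
length of 600 ms.  ``healthy_config()`` is an uncalibrated sanity variant
with both remodeling factors removed.  Every parameter can be overridden
through a YAML file with the blocks ``calcium``, ``myofilament``, ``lv``,
``rv``, ``circulation``, ``leak``, ``lvad`` and ``blood``.
"""

from __future__ import annotations

from dataclasses import asdict, replace

import yaml

from .calcium import CaTransientParams
from .chambers import VentricleParams
from .circulation import CircParams, LvadConfig, ModelConfig
from .myofilament import MyofilamentParams

__all__ = ["baseline_config", "healthy_config", "load_config", "save_config"]

HF_PASSIVE_SCALE = 5.0
HF_CA_FACTOR = 0.3


def baseline_config() -> ModelConfig:
    """Failing-heart fixture (pre-calibration).

    The contractile gain and total blood volume are starting values for
    :func:`cvloop.experiments.calibrate_baseline`, which pins the
    control/normal cell to SV 20 mL at EDV 100 mL (EF 20%).
    """
    return ModelConfig(
        calcium=CaTransientParams(hf_amplitude_factor=HF_CA_FACTOR),
        myofilament=MyofilamentParams(),
        lv=VentricleParams(v0=10.0, beta=0.15, kappa=0.028,
                           passive_scale=HF_PASSIVE_SCALE,
                           sl_ref=1.7, v_ref=100.0, p_act_gain=2.5),
        rv=VentricleParams(v0=8.0, beta=0.12, kappa=0.04,
                           passive_scale=HF_PASSIVE_SCALE,
                           sl_ref=2.1, v_ref=70.0, p_act_gain=0.45),
        circ=CircParams(),
        lvad=LvadConfig(),
        total_blood_volume=1000.0,
    )


def healthy_config() -> ModelConfig:
    """Non-remodeled sanity fixture: normal stiffness and calcium amplitude.

    Not calibrated to any phenotype; useful for qualitative comparison only.
    """
    base = baseline_config()
    return base.with_(
        calcium=replace(base.calcium, hf_amplitude_factor=1.0),
        lv=replace(base.lv, passive_scale=1.0),
        rv=replace(base.rv, passive_scale=1.0),
    )


# YAML field names (ms / uM suffixes) -> CaTransientParams fields
_CA_KEYS = {
    "bcl_ms": "bcl",
    "ca_diastolic_uM": "ca_diastolic",
    "ca_amplitude_uM": "ca_amplitude",
    "tau_rise_ms": "tau_rise",
    "tau_decay_ms": "tau_decay",
    "hf_amplitude_factor": "hf_amplitude_factor",
}


def _to_yaml_dict(cfg: ModelConfig) -> dict:
    ca = asdict(cfg.calcium)
    circ = asdict(cfg.circ)
    sf_mi = circ.pop("sf_mi")
    sf_ao = circ.pop("sf_ao")
    return {
        "calcium": {yk: ca[fk] for yk, fk in _CA_KEYS.items()},
        "myofilament": asdict(cfg.myofilament),
        "lv": asdict(cfg.lv),
        "rv": asdict(cfg.rv),
        "circulation": circ,
        "leak": {"sf_mi": sf_mi, "sf_ao": sf_ao},
        "lvad": {"mode": cfg.lvad.mode, "flow_ml_s": cfg.lvad.flow},
        "blood": {"total_volume_ml": cfg.total_blood_volume},
    }


def save_config(cfg: ModelConfig, path) -> None:
    """Serialize a configuration to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_yaml_dict(cfg), fh, sort_keys=False)


def load_config(path) -> ModelConfig:
    """Load a configuration from YAML; missing blocks fall back to the fixture."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = baseline_config()

    ca_raw = raw.get("calcium", {})
    unknown = set(ca_raw) - set(_CA_KEYS)
    if unknown:
        raise ValueError(f"unknown calcium keys: {sorted(unknown)}")
    calcium = replace(base.calcium, **{_CA_KEYS[k]: v for k, v in ca_raw.items()})

    myof = replace(base.myofilament, **raw.get("myofilament", {}))
    lv = replace(base.lv, **raw.get("lv", {}))
    rv = replace(base.rv, **raw.get("rv", {}))
    circ = replace(base.circ, **raw.get("circulation", {}), **raw.get("leak", {}))
    lvad_raw = raw.get("lvad", {})
    lvad = LvadConfig(mode=lvad_raw.get("mode", "none"),
                      flow=lvad_raw.get("flow_ml_s", 0.0))
    total = raw.get("blood", {}).get("total_volume_ml", base.total_blood_volume)

    return ModelConfig(calcium=calcium, myofilament=myof, lv=lv, rv=rv,
                       circ=circ, lvad=lvad, total_blood_volume=total)
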