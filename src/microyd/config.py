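"""Configuration loading: bundled defaults plus optional user overrides."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .dielectric import DielectricModel, OscillatorChannel


def load_config(path: str | Path | None = None) -> dict:
    """Load the bundled YAML configuration, optionally deep-merged with a
    user file (user values win)."""
    with resources.files("microyd.data").joinpath("water_drude.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def build_dielectric_model(cfg: dict | None = None) -> DielectricModel:
    """Construct (and validate) the dielectric model from a config dict."""
    if cfg is None:
        cfg = load_config()
    block = cfg["dielectric"]
    channels = [
        OscillatorChannel(
            kind=ch["kind"],
            label=ch["label"],
            threshold_eV=float(ch["threshold_eV"]),
            resonance_eV=float(ch["resonance_eV"]),
            gamma_eV=float(ch["gamma_eV"]),
            amplitude_eV2=float(ch["amplitude_eV2"]),
            dispersion=ch.get("dispersion", "quadratic"),
        )
        for ch in block["channels"]
    ]
    model = DielectricModel(
        channels,
        molecular_density_per_cm3=float(block["molecular_density_per_cm3"]),
        sum_rule_tolerance=float(block.get("sum_rule_tolerance", 0.10)),
    )
    model.excitation_q_cutoff_eV = float(block.get("excitation_q_cutoff_eV", 100.0))
    return model


def delta_table_keV(cfg: dict | None = None) -> dict[float, float]:
    if cfg is None:
        cfg = load_config()
    return {float(k): float(v) for k, v in cfg["targets"]["delta_keV"].items()}
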