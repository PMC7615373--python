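"""YAML serialization of the complete device configuration.

The exported YAML is the hand-off artifact from the configuration workbench
to the implanted device, so validation is strict: unknown keys are rejected
by name (a misspelled key silently falling back to a default would be a
safety hazard), every numeric field is type-checked, and all component
invariants are re-validated on import.  Units are encoded in the key names
(``threshold_uv``, ``debounce_s``, ``band_low_hz``...).

Schema (see ``docs/config-schema.md``)::

    chain:       sampling_rate_hz, highpass_hz, band_low_hz, band_center_hz,
                 band_high_hz, smoothing_hz, order
    classifier:  threshold_uv, debounce_s, log_resolution_s, log_capacity
    programs:    nonevent / event, each {id, amplitude_ma, frequency_hz,
                 pulse_width_us, recharge}
    meta:        free-form provenance mapping

Only ``chain.band_low_hz``, ``chain.band_high_hz`` and
``classifier.threshold_uv`` are required; every other field has the
documented device default (highpass 6.8 Hz, smoothing 1 Hz, 625 Hz sampling,
2 s debounce, 1 s log resolution, 1200-entry log, 1 mA / 3 mA programs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from numbers import Real
from pathlib import Path

import yaml

from .classifier import ClassifierConfig, StimProgram, default_programs
from .signal_chain import FilterChainConfig

__all__ = ["DeviceConfig", "ConfigError", "export_config", "import_config"]


class ConfigError(ValueError):
    """A device-configuration file failed validation."""


@dataclass
class DeviceConfig:
    """Filter chain + classifier settings plus free-form provenance metadata."""

    chain: FilterChainConfig
    classifier: ClassifierConfig
    meta: dict = field(default_factory=dict)


_CHAIN_KEYS = {
    "sampling_rate_hz": ("sampling_rate", 625.0),
    "highpass_hz": ("highpass_hz", 6.8),
    "band_low_hz": ("band_low_hz", None),
    "band_center_hz": ("band_center_hz", "MID"),  # default: band midpoint
    "band_high_hz": ("band_high_hz", None),
    "smoothing_hz": ("smoothing_hz", 1.0),
    "order": ("order", 2),
}
_CLASSIFIER_KEYS = {
    "threshold_uv": ("threshold_uv", None),
    "debounce_s": ("debounce_s", 2.0),
    "log_resolution_s": ("log_resolution_s", 1.0),
    "log_capacity": ("log_capacity", 1200),
}
_PROGRAM_KEYS = {"id", "amplitude_ma", "frequency_hz", "pulse_width_us", "recharge"}


def export_config(cfg: DeviceConfig, path: str | Path) -> None:
    """Write a validated device configuration as YAML (keys in schema order)."""
    if not isinstance(cfg.chain, FilterChainConfig):
        raise ConfigError("chain must be a FilterChainConfig")
    if not isinstance(cfg.classifier, ClassifierConfig):
        raise ConfigError("classifier must be a ClassifierConfig")
    # re-run invariant checks in case fields were mutated after construction
    cfg.chain.__post_init__()
    cfg.classifier.__post_init__()
    doc = {
        "chain": {
            "sampling_rate_hz": cfg.chain.sampling_rate,
            "highpass_hz": cfg.chain.highpass_hz,
            "band_low_hz": cfg.chain.band_low_hz,
            "band_center_hz": cfg.chain.band_center_hz,
            "band_high_hz": cfg.chain.band_high_hz,
            "smoothing_hz": cfg.chain.smoothing_hz,
            "order": cfg.chain.order,
        },
        "classifier": {
            "threshold_uv": cfg.classifier.threshold_uv,
            "debounce_s": cfg.classifier.debounce_s,
            "log_resolution_s": cfg.classifier.log_resolution_s,
            "log_capacity": cfg.classifier.log_capacity,
        },
        "programs": {
            "nonevent": _program_to_dict(cfg.classifier.program_nonevent),
            "event": _program_to_dict(cfg.classifier.program_event),
        },
        "meta": dict(cfg.meta),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _program_to_dict(p: StimProgram) -> dict:
    return {
        "id": p.id,
        "amplitude_ma": p.amplitude_ma,
        "frequency_hz": p.frequency_hz,
        "pulse_width_us": p.pulse_width_us,
        "recharge": p.recharge,
    }


def _require_mapping(obj, name: str) -> dict:
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    return obj


def _reject_unknown(section: dict, allowed, name: str) -> None:
    unknown = sorted(set(section) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown key(s) in {name!r}: {', '.join(unknown)}")


def _number(section: dict, key: str, default, name: str, integer: bool = False):
    if key not in section:
        if default is None:
            raise ConfigError(f"missing required key {name}.{key}")
        return default
    v = section[key]
    if isinstance(v, bool) or not isinstance(v, Real):
        raise ConfigError(f"{name}.{key} must be a number, got {type(v).__name__}")
    return int(v) if integer else float(v)


def _parse_program(section, default: StimProgram, name: str) -> StimProgram:
    if section is None:
        return default
    section = _require_mapping(section, name)
    _reject_unknown(section, _PROGRAM_KEYS, name)
    pid = section.get("id", default.id)
    if not isinstance(pid, str):
        raise ConfigError(f"{name}.id must be a string")
    recharge = section.get("recharge", default.recharge)
    if not isinstance(recharge, str):
        raise ConfigError(f"{name}.recharge must be a string")
    try:
        return StimProgram(
            id=pid,
            amplitude_ma=_number(section, "amplitude_ma", default.amplitude_ma, name),
            frequency_hz=_number(section, "frequency_hz", default.frequency_hz, name),
            pulse_width_us=_number(
                section, "pulse_width_us", default.pulse_width_us, name
            ),
            recharge=recharge,
        )
    except ValueError as exc:
        raise ConfigError(f"invalid {name}: {exc}") from exc


def import_config(path: str | Path) -> DeviceConfig:
    """Read and strictly validate a device-configuration YAML file."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path} is not valid YAML: {exc}") from exc
    doc = _require_mapping(doc, "document")
    _reject_unknown(doc, {"chain", "classifier", "programs", "meta"}, "document")

    chain_sec = _require_mapping(doc.get("chain"), "chain")
    _reject_unknown(chain_sec, _CHAIN_KEYS, "chain")
    chain_kwargs = {}
    for key, (attr, default) in _CHAIN_KEYS.items():
        if default == "MID" and key not in chain_sec:
            continue  # band_center defaults to the band midpoint below
        chain_kwargs[attr] = _number(
            chain_sec, key, None if default == "MID" else default, "chain",
            integer=(attr == "order"),
        )
    if "band_center_hz" not in chain_kwargs:
        chain_kwargs["band_center_hz"] = (
            chain_kwargs["band_low_hz"] + chain_kwargs["band_high_hz"]
        ) / 2.0

    clf_sec = _require_mapping(doc.get("classifier"), "classifier")
    _reject_unknown(clf_sec, _CLASSIFIER_KEYS, "classifier")
    clf_kwargs = {
        attr: _number(clf_sec, key, default, "classifier",
                      integer=(attr == "log_capacity"))
        for key, (attr, default) in _CLASSIFIER_KEYS.items()
    }

    prog_sec = _require_mapping(doc.get("programs"), "programs")
    _reject_unknown(prog_sec, {"nonevent", "event"}, "programs")
    p0_default, p1_default = default_programs()
    p0 = _parse_program(prog_sec.get("nonevent"), p0_default, "programs.nonevent")
    p1 = _parse_program(prog_sec.get("event"), p1_default, "programs.event")

    meta = _require_mapping(doc.get("meta"), "meta")

    try:
        chain = FilterChainConfig(**chain_kwargs)
    except ValueError as exc:
        raise ConfigError(f"invalid chain: {exc}") from exc
    try:
        clf = ClassifierConfig(
            program_nonevent=p0, program_event=p1, **clf_kwargs
        )
    except ValueError as exc:
        raise ConfigError(f"invalid classifier: {exc}") from exc
    return DeviceConfig(chain=chain, classifier=clf, meta=meta)
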