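"""Run configuration: defaults for every tunable constant, YAML override."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .units import DEFAULT_CHAMBER_VOLUMES_L, ChamberMethod

__all__ = ["RunConfig", "DEFAULT_DRY_TO_FRESH_COMBINED_FACTOR"]

# Zero-intercept least-squares factor mapping published μg HCN per g dry
# foliage onto μmol HCN per g fresh weight; encodes an assumed tissue water
# content (dry:fresh mass ratio ≈ 0.208) together with the 27.03 g/mol molar
# mass of HCN.
DEFAULT_DRY_TO_FRESH_COMBINED_FACTOR = 0.00769305


@dataclass
class RunConfig:
    """All knobs of the analysis pipeline with their field-protocol defaults.

    Unknown keys in a config file are rejected so that typos fail loudly.
    """

    cup_volume_l: float = DEFAULT_CHAMBER_VOLUMES_L[ChamberMethod.CUP]
    mortar_pestle_volume_l: float = DEFAULT_CHAMBER_VOLUMES_L[ChamberMethod.MORTAR_PESTLE]
    jar_volume_l: float = DEFAULT_CHAMBER_VOLUMES_L[ChamberMethod.JAR]
    calibration_factor: float = 10.2
    detection_limit_ppm: float = 0.3
    dry_to_fresh_combined_factor: float = DEFAULT_DRY_TO_FRESH_COMBINED_FACTOR
    polynomial_degree: int = 4
    kinetics_threshold_min: float = 20.0
    output_dir: str = "."
    verbosity: str = "info"

    def __post_init__(self) -> None:
        for name in (
            "cup_volume_l",
            "mortar_pestle_volume_l",
            "jar_volume_l",
            "calibration_factor",
            "detection_limit_ppm",
            "dry_to_fresh_combined_factor",
            "kinetics_threshold_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if self.polynomial_degree < 1:
            raise ValueError("polynomial_degree must be >= 1")

    def chamber_volume(self, method: str | ChamberMethod) -> float:
        method = ChamberMethod(method)
        return {
            ChamberMethod.CUP: self.cup_volume_l,
            ChamberMethod.MORTAR_PESTLE: self.mortar_pestle_volume_l,
            ChamberMethod.JAR: self.jar_volume_l,
        }[method]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config file; flat keys or nested ``chambers.<method>.volume_liters``."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        kwargs: dict = {}
        chambers = raw.pop("chambers", {})
        alias = {"cup": "cup_volume_l", "mortar_pestle": "mortar_pestle_volume_l", "jar": "jar_volume_l"}
        for method, spec in chambers.items():
            if method not in alias or not isinstance(spec, dict) or set(spec) - {"volume_liters"}:
                raise ValueError(f"unknown chamber config entry: {method}={spec}")
            kwargs[alias[method]] = spec["volume_liters"]
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)
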