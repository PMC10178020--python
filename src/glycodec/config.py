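"""Pipeline configuration: one named key per adjustable constant.

The defaults reproduce the published decomposer / composition-generator
configuration exactly. A flat key-value YAML file can override any subset
of them; keys keep the same names as the dataclass fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from .masses import (
    DEFAULT_BOUNDS,
    DEFAULT_OXONIUM_IONS,
    DEFAULT_PATTERN_OFFSETS,
    ISOTOPE_SPACING,
    MONOSACCHARIDE_MASSES,
    MonosaccharideTable,
    OxoniumTable,
    PatternTemplate,
)


@dataclass
class Config:
    # spectrum prefilter
    min_peak_intensity: float = 15.0
    # oxonium filter
    oxonium_tolerance: float = 0.02
    min_oxonium_ions: int = 1
    oxonium_sum_threshold: float = 0.0047
    oxonium_ions: dict = field(default_factory=lambda: dict(DEFAULT_OXONIUM_IONS))
    # core pattern finder
    pattern_offsets: list = field(default_factory=lambda: list(DEFAULT_PATTERN_OFFSETS))
    min_reference_mz: float = 850.0
    min_reference_rel_intensity: float = 0.1
    pattern_tolerance: float = 0.05
    min_pattern_peaks: int = 2
    isotope_spacing: float = ISOTOPE_SPACING
    isotope_k_max: int = 3
    # deconvolution
    merge_tolerance: float = 0.001
    # composition generator
    monosaccharide_masses: dict = field(
        default_factory=lambda: dict(MONOSACCHARIDE_MASSES)
    )
    monosaccharide_bounds: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_BOUNDS.items()}
    )
    composition_tolerance: float = 0.1
    # identification comparison
    identity_mass_tolerance: float = 0.05
    identity_max_isotopes: int = 3

    def __post_init__(self) -> None:
        for name in (
            "oxonium_tolerance",
            "pattern_tolerance",
            "composition_tolerance",
            "merge_tolerance",
            "identity_mass_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_peak_intensity < 0:
            raise ValueError("min_peak_intensity must be >= 0")
        # construction validates entries
        self.pattern_template()
        self.oxonium_table()
        self.monosaccharide_table()

    def oxonium_table(self) -> OxoniumTable:
        return OxoniumTable(tuple(self.oxonium_ions.items()))

    def pattern_template(self) -> PatternTemplate:
        return PatternTemplate(tuple(self.pattern_offsets))

    def monosaccharide_table(self) -> MonosaccharideTable:
        return MonosaccharideTable(
            masses=dict(self.monosaccharide_masses),
            bounds={k: tuple(v) for k, v in self.monosaccharide_bounds.items()},
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Build a :class:`Config` from an optional YAML file plus overrides.

    The file holds a flat mapping of field names to values; unknown keys
    are rejected. With no file and no overrides this equals ``Config()``.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ValueError(f"config file {path} must hold a key-value mapping")
        values.update(loaded)
    values.update(overrides)
    known = set(Config.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return Config(**values)


def dump_config(config: Config, path: str | Path) -> None:
    """Write the full effective configuration as flat YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
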