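"""Run configuration: file paths, buffer constants, study windows, seed.

All defaults are the analysis constants the pipeline is built around: an
800-m network radius, a 50-m centerline offset, a 15-km distance cap, and
index/history windows of August 2011 – August 2012 and January 2008
onward.  Configuration may come from a TOML file plus keyword overrides.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

from .anthropometry import StudyWindows
from .errors import ConfigError


@dataclass
class RunConfig:
    out_dir: str = "walkbmi_out"
    streets: str = "streets.geojson"
    openspace: str = "openspace.geojson"
    businesses: str = "businesses.geojson"
    tracts: str = "tracts.geojson"
    cohort: str = "cohort.csv"
    growth_reference: str | None = None  # CSV drop-in; None -> synthetic
    stature_reference: str | None = None
    buffer_radius_m: float = 800.0
    buffer_offset_m: float = 50.0
    distance_cap_km: float = 15.0
    max_offset_m: float = 500.0
    index_start: date = date(2011, 8, 1)
    index_end: date = date(2012, 8, 31)
    history_start: date = date(2008, 1, 1)
    seed: int = 0
    n_children: int = 2000
    n_homes: int = 400
    min_stratum: int = 50

    def __post_init__(self) -> None:
        if self.buffer_radius_m <= 0 or self.buffer_offset_m <= 0:
            raise ConfigError("buffer radius and offset must be positive")
        if self.distance_cap_km <= 0:
            raise ConfigError("distance cap must be positive")
        for f_ in ("index_start", "index_end", "history_start"):
            v = getattr(self, f_)
            if isinstance(v, str):
                setattr(self, f_, date.fromisoformat(v))
        if not (self.history_start <= self.index_start <= self.index_end):
            raise ConfigError("study windows must satisfy history <= index start <= end")

    @property
    def windows(self) -> StudyWindows:
        return StudyWindows(self.index_start, self.index_end, self.history_start)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def digest(self) -> str:
        payload = {k: str(v) for k, v in sorted(asdict(self).items())}
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:16]

    def path(self, name: str) -> Path:
        p = Path(getattr(self, name))
        if p.is_absolute():
            return p
        return Path(self.out_dir) / p
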