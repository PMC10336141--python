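"""Run configuration: one serialisable object echoed into every output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .exceptions import InvalidParameterError


@dataclass
class RunConfig:
    epoch_seconds: int = 60
    window_epochs: int | None = None        # None -> day-aligned default
    circadian_band_minutes: tuple[float, float] = (1320.0, 1560.0)
    rank: int = 50
    energy_basis: str = "singular_values"   # or "series"
    ra_method: str = "profile"
    seed: int = 0
    log_level: str = "INFO"
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.circadian_band_minutes = tuple(float(v) for v in self.circadian_band_minutes)
        if self.energy_basis not in ("singular_values", "series"):
            raise InvalidParameterError(f"unknown energy_basis {self.energy_basis!r}")
        if self.rank < 1:
            raise InvalidParameterError("rank must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["circadian_band_minutes"] = list(self.circadian_band_minutes)
        return d

    def hash(self) -> str:
        """Stable digest of the configuration, for output audit trails."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
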