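"""User-tunable analysis configuration and its flat-file serialization."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All user-tunable analysis parameters.

    ``sigmas`` are Gaussian scales in pixels; the user-facing vessel
    *diameter* d maps to sigma = d/2 (see :func:`from_diameters`).
    Intensity thresholds (``low``, ``high``) and the vesselness threshold
    (``v_min``) are normalized to [0, 1]. Defaults analyse the synthetic
    tree fixtures correctly out of the box.
    """

    sigmas: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0)
    beta: float = 0.5
    c: float | None = None
    gamma: float = 2.0
    v_min: float = 0.08
    low: float = 0.1
    high: float = 1.0
    min_particle: int = 25
    max_hole: int = 25
    pixel_size: float = 1.0
    unit_area: float = 1.0e4
    lacunarity_region: str = "hull_bbox"
    lacunarity_boxes: tuple[int, ...] | None = None
    channel_policy: str = "max_channel"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigmas", tuple(float(s) for s in self.sigmas))
        if self.lacunarity_boxes is not None:
            object.__setattr__(
                self, "lacunarity_boxes", tuple(int(b) for b in self.lacunarity_boxes)
            )
        if not self.sigmas or any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be nonempty and positive")
        for name in ("v_min", "low", "high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.low > self.high:
            raise ValueError("low must not exceed high")
        if self.min_particle < 0 or self.max_hole < 0:
            raise ValueError("min_particle and max_hole must be non-negative")
        if self.pixel_size <= 0 or self.unit_area <= 0:
            raise ValueError("pixel_size and unit_area must be positive")
        if self.lacunarity_region not in ("image", "hull_bbox"):
            raise ValueError(
                f"lacunarity_region must be 'image' or 'hull_bbox', "
                f"got {self.lacunarity_region!r}"
            )
        if self.lacunarity_boxes is not None and any(
            b < 1 for b in self.lacunarity_boxes
        ):
            raise ValueError("lacunarity box sizes must be >= 1")
        if self.beta <= 0 or self.gamma < 0:
            raise ValueError("beta must be positive and gamma non-negative")
        if self.c is not None and self.c <= 0:
            raise ValueError("c must be positive or None (auto)")

    @classmethod
    def from_diameters(cls, diameters, **kwargs) -> "AnalysisConfig":
        """Build a config from user-facing vessel diameters (sigma = d/2)."""
        return cls(sigmas=tuple(d / 2.0 for d in diameters), **kwargs)

    # -- flat key-value (TOML) round trip ---------------------------------

    def to_toml(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if val is None:
                continue  # absent key means auto
            if isinstance(val, tuple):
                items = ", ".join(format(v, "g") if isinstance(v, float) else str(v) for v in val)
                lines.append(f"{f.name} = [{items}]")
            elif isinstance(val, str):
                lines.append(f'{f.name} = "{val}"')
            elif isinstance(val, bool):
                lines.append(f"{f.name} = {str(val).lower()}")
            elif isinstance(val, float):
                lines.append(f"{f.name} = {val!r}")
            else:
                lines.append(f"{f.name} = {val}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        Path(path).write_text(self.to_toml())

    @classmethod
    def from_toml(cls, text: str) -> "AnalysisConfig":
        data = tomllib.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sigmas", "lacunarity_boxes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        return cls.from_toml(Path(path).read_text())
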