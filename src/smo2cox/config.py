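"""Run configuration: a single validated YAML file driving the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .detection import DEFAULT_REGION, DEFAULT_WINDOW_S, PlateauCriterion


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline settings; unknown keys are rejected.

    criterion_battery maps criterion ids (A5, A10, R5, R10 by convention) to
    {mode, threshold} dicts; window/region/metric settings apply to all.
    """

    manifest: str | None = None
    output_dir: str = "results"
    ma_width_s: float = 5.0
    max_gap_s: float = 4.0
    center_ma: bool = False
    force_smooth: bool = False
    interpolation: str = "linear"
    window_s: int = DEFAULT_WINDOW_S
    region: tuple[int, int] = DEFAULT_REGION
    stability_metric: str = "anchored"
    criterion_battery: dict[str, dict] = field(
        default_factory=lambda: {
            "A5": {"mode": "absolute", "threshold": 5.0},
            "A10": {"mode": "absolute", "threshold": 10.0},
            "R5": {"mode": "relative", "threshold": 5.0},
            "R10": {"mode": "relative", "threshold": 10.0},
        }
    )
    consensus_min_agree: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interpolation != "linear":
            raise ConfigError(
                f"unsupported interpolation {self.interpolation!r}"
            )
        if self.stability_metric not in ("anchored", "range"):
            raise ConfigError(
                f"unknown stability_metric {self.stability_metric!r}"
            )
        self.region = tuple(self.region)  # type: ignore[assignment]

    def criteria(self) -> dict[str, PlateauCriterion]:
        return {
            cid: PlateauCriterion(
                mode=spec["mode"],
                threshold=float(spec["threshold"]),
                window_s=self.window_s,
                region=self.region,
                stability_metric=self.stability_metric,
            )
            for cid, spec in self.criterion_battery.items()
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config must be a mapping: {path}")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
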