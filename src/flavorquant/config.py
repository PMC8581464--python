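"""Run configuration: acceptance constants and model choices in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

ALLOWED_MODELS = ("linear", "quadratic")
ALLOWED_WEIGHTINGS = ("1/x^2", "1/x", "none")


@dataclass
class RunConfig:
    """Pipeline configuration with the method's acceptance constants.

    Defaults encode the validation conventions: +/-20% bias/precision
    acceptance, carryover below 5% of the reported LLOQ, stability
    recovery within 80-120%, |drift| within 20% (diagnostic).
    """

    panel_path: str | None = None
    model: str = "quadratic"
    weighting: str = "1/x^2"
    acceptance: float = 20.0
    carryover_limit: float = 5.0
    stability_window: tuple[float, float] = (80.0, 120.0)
    drift_limit: float = 20.0
    reject_on_qc_failure: bool = False
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        if self.model not in ALLOWED_MODELS:
            raise ConfigError(f"model must be one of {ALLOWED_MODELS}")
        if self.weighting not in ALLOWED_WEIGHTINGS:
            raise ConfigError(f"weighting must be one of {ALLOWED_WEIGHTINGS}")
        for name in ("acceptance", "carryover_limit", "drift_limit"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.stability_window
        if not (0 <= lo < hi):
            raise ConfigError("stability window must satisfy 0 <= low < high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a key-value mapping")
        if "stability_window" in raw:
            raw["stability_window"] = tuple(raw["stability_window"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config key in {path}: {exc}") from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stability_window"] = list(self.stability_window)
        return d
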