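"""Run configuration: one validated record composing all pipeline settings."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .params import RCParams, WindowConfig
from .synth import BreathingSpec

MODES = ("realtime", "fixed_rc", "ridge_only")


@dataclass(frozen=True)
class RunConfig:
    """Composition of reservoir, window and input settings for one run.

    ``breathing`` and ``input_path`` are mutually exclusive input sources:
    either a synthetic trace is generated from the spec, or a recorded
    two-column CSV (time_s, position_mm) is loaded.
    """

    rc: RCParams = field(default_factory=RCParams)
    window: WindowConfig = field(default_factory=WindowConfig)
    breathing: BreathingSpec | None = None
    input_path: str | None = None
    mode: str = "realtime"
    out_dir: str = "respirc_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InvalidParameterError(
                f"mode must be one of {MODES}, got {self.mode!r}"
            )
        if self.breathing is not None and self.input_path is not None:
            raise InvalidParameterError(
                "breathing spec and input_path are mutually exclusive"
            )
        # cross-field constraints (k_tr > k_w + h_p etc.) are enforced by
        # WindowConfig/RCParams themselves at construction

    def to_dict(self) -> dict:
        return {
            "rc": self.rc.to_dict(),
            "window": self.window.to_dict(),
            "breathing": json.loads(self.breathing.to_json()) if self.breathing else None,
            "input_path": self.input_path,
            "mode": self.mode,
            "out_dir": self.out_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        rc = RCParams.from_dict(d["rc"]) if d.get("rc") else RCParams()
        window = WindowConfig.from_dict(d["window"]) if d.get("window") else WindowConfig()
        breathing = None
        if d.get("breathing"):
            breathing = BreathingSpec.from_json(json.dumps(d["breathing"]))
        return cls(
            rc=rc,
            window=window,
            breathing=breathing,
            input_path=d.get("input_path"),
            mode=d.get("mode", "realtime"),
            out_dir=d.get("out_dir", "respirc_out"),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
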