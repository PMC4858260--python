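"""JSON configuration for the CLI drivers.

A config file is a JSON object with optional blocks; anything omitted takes
the model's defaults.  Example::

    {
      "detector": {"delay_mode": "dynamic", "tau1": 5.0, "tau2": 15.0,
                   "F": 0.25, "rect_mode": "offset_only"},
      "controller": {"control_dt": 2.0},
      "protocol": {"duration": 5.0, "start_speed": 40.0},
      "stimulus": {"wavelength": 38.0, "contrast": 1.0, "waveform": "square"}
    }
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

from .core import ConfigurationError
from .detector import AVDUParams
from .experiments import TrialProtocol
from .flight import ControllerParams

__all__ = ["load_config", "RunConfig"]


def _build(cls, block: dict[str, Any], name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ConfigurationError(f"unknown keys in {name!r} block: {sorted(unknown)}")
    return cls(**block)


@dataclasses.dataclass
class RunConfig:
    detector: AVDUParams
    controller: ControllerParams
    protocol: TrialProtocol
    stimulus: dict[str, Any]
    raw: dict[str, Any]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a JSON config file; ``None`` gives all defaults."""
    raw: dict[str, Any] = {}
    if path is not None:
        raw = json.loads(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError("config root must be a JSON object")
    return RunConfig(
        detector=_build(AVDUParams, raw.get("detector", {}), "detector"),
        controller=_build(ControllerParams, raw.get("controller", {}), "controller"),
        protocol=_build(TrialProtocol, raw.get("protocol", {}), "protocol"),
        stimulus=dict(raw.get("stimulus", {})),
        raw=raw,
    )
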