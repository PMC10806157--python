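"""Simulation configuration: defaults, provenance notes, YAML round trip
and deterministic seed fan-out.

A single master seed is fanned out into independent per-component streams
(beat timing, motion, scenario, camera noise, breathing-rate draw) so that
toggling one component never shifts another component's random draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import InvalidParameterError
from .scenario import SCENARIO_NAMES

__all__ = ["SimulationConfig", "FIELD_NOTES", "derive_seeds"]

#: plain-language provenance note for every schema default
FIELD_NOTES: dict[str, str] = {
    "hr": "mean heart rate in beats/min; reference synthetic-waveform configuration uses 70",
    "ibi_mod_freq": "inter-beat-interval modulation frequency in Hz (HRV); reference configuration uses 0.3",
    "ibi_mod_depth": "IBI modulation depth as a fraction of the mean IBI; package default, not a printed value",
    "breath_freq": "breathing frequency in Hz; drawn once per video from the physiological 0.13-0.4 Hz band when null",
    "theta_mean": "mean neck-rotation amplitude of the BCG motion, degrees (0.12)",
    "theta_sd": "beat-to-beat spread of the neck-rotation amplitude, degrees (0.03)",
    "beta": "per-channel cardiac weights for R, G, B (0.33, 0.77, 0.53)",
    "skin_tone": "skin-tone class I (lightest) .. VI (darkest) selecting the base reflectance",
    "scenario": "one of stable, expression_talk, light_change, physical_activity",
    "width": "frame width in pixels; 64 is the desk-scale default, 640x360 mirrors the full render geometry",
    "height": "frame height in pixels",
    "fps": "video frame rate in Hz; renders use 25",
    "duration": "video duration in seconds",
    "noise_sigma": "camera-noise standard deviation in [0,1] intensity units; package default, not a printed value",
    "pulse_scale": "pulsatile color amplitude relative to intensity units (about 1% green-channel modulation)",
    "pulse_mode": "additive: subsurface pulse adds to reflectance; multiplicative: pulse rides on base reflectance",
    "texture_contrast": "relative contrast of the static surface-texture layer",
    "illumination_I0": "baseline relative illumination (constant under stable laboratory light)",
    "bcg_gain": "intensity units per degree of neck rotation for the motion artifact m(t)",
    "breath_gain": "intensity units per normalized scene unit of breathing displacement",
    "motion_enabled": "disable to render a motion-free video (m(t) = 0)",
    "seed": "master seed; fanned out deterministically to all random components",
}


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable parameters of one simulated video."""

    hr: float = 70.0
    ibi_mod_freq: float = 0.3
    ibi_mod_depth: float = 0.05
    breath_freq: float | None = None
    theta_mean: float = 0.12
    theta_sd: float = 0.03
    beta: tuple[float, float, float] = (0.33, 0.77, 0.53)
    skin_tone: str = "III"
    scenario: str = "stable"
    width: int = 64
    height: int = 64
    fps: float = 25.0
    duration: float = 10.0
    noise_sigma: float = 0.002
    pulse_scale: float = 0.01
    pulse_mode: str = "additive"
    texture_contrast: float = 0.05
    illumination_I0: float = 1.0
    bcg_gain: float = 0.0045
    breath_gain: float = 0.01
    motion_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_NAMES:
            raise InvalidParameterError(
                f"scenario must be one of {SCENARIO_NAMES}, got {self.scenario!r}"
            )
        if self.duration <= 0 or self.fps <= 0:
            raise InvalidParameterError("duration and fps must be positive")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta"] = list(self.beta)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        if "beta" in d and d["beta"] is not None:
            d["beta"] = tuple(d["beta"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))

    def with_updates(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def schema_notes(cls) -> dict[str, str]:
        return dict(FIELD_NOTES)


def derive_seeds(master: int) -> dict[str, int]:
    """Fan a master seed out into fixed, independent per-component seeds."""
    ss = np.random.SeedSequence(int(master))
    names = ("ppg", "motion", "scenario", "noise", "breath")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }
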