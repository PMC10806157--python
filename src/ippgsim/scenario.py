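"""Action scheduling and benchmark scenarios.

Actions (blinks, expressions, talking, gait cycles, light transitions) are
scheduled either periodically — events at frames ``i*step`` for
``i in range(int(framenum/step))`` — or non-periodically, by repeatedly
advancing a frame cursor by a random step drawn from {1..j} and inserting
an event at the new cursor position.  In a patch-level simulator each
pattern is realised as a transient multiplicative illumination perturbation
and/or a motion-gain boost with a raised-cosine envelope, which is the
pathway by which facial movements and physical activity disturb the
recorded intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "ActionEvent",
    "ScenarioSpec",
    "SCENARIO_NAMES",
    "PATTERNS",
    "schedule_periodic",
    "schedule_nonperiodic",
    "build_scenario",
    "scenario_modulation",
]

SCENARIO_NAMES = ("stable", "expression_talk", "light_change", "physical_activity")


@dataclass(frozen=True)
class PatternSpec:
    """How an action pattern perturbs the scene.

    ``illum`` scales the event magnitude into a multiplicative illumination
    perturbation; ``motion_boost`` scales it into a transient motion-gain
    increase.  Either may be zero.
    """

    illum: float = 1.0
    motion_boost: float = 0.0


# what each named pattern does to illumination / motion gain
PATTERNS: dict[str, PatternSpec] = {
    "blink": PatternSpec(illum=-1.0),
    "expression": PatternSpec(illum=1.0),
    "talk": PatternSpec(illum=1.0, motion_boost=0.5),
    "light_ramp": PatternSpec(illum=1.0),
    "gait": PatternSpec(illum=1.0, motion_boost=1.0),
}


@dataclass(frozen=True)
class ActionEvent:
    frame_key: int
    pattern_id: str
    duration_frames: int = 1
    magnitude: float = 0.05

    def __post_init__(self) -> None:
        if self.frame_key < 0:
            raise InvalidParameterError("frame_key must be >= 0")
        if self.duration_frames < 1:
            raise InvalidParameterError("duration_frames must be >= 1")
        if self.pattern_id not in PATTERNS:
            raise InvalidParameterError(f"unknown pattern {self.pattern_id!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    framenum: int
    events: tuple[ActionEvent, ...] = ()
    illumination_profile_id: str = "constant"
    motion_gain_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise InvalidParameterError(
                f"scenario must be one of {SCENARIO_NAMES}, got {self.name!r}"
            )
        keys = [e.frame_key for e in self.events]
        if keys != sorted(keys):
            raise InvalidParameterError("events must be sorted by frame_key")
        if any(k > self.framenum for k in keys):
            raise InvalidParameterError("event frame_key exceeds framenum")


def schedule_periodic(framenum: int, step: int, pattern_id: str, **event_kw) -> list[ActionEvent]:
    """Insert an event every ``step`` frames: keys i*step, i = 0..int(M/step)-1."""
    if step < 1:
        raise InvalidParameterError("step must be >= 1")
    if framenum < step:
        raise InvalidParameterError("framenum must be >= step")
    return [
        ActionEvent(frame_key=i * step, pattern_id=pattern_id, **event_kw)
        for i in range(int(framenum / step))
    ]


def schedule_nonperiodic(
    framenum: int, j: int, pattern_id: str, seed: int | None = None, **event_kw
) -> list[ActionEvent]:
    """Insert events at randomly spaced frames with gaps drawn from {1..j}.

    The cursor advances by the drawn step each iteration (a zero step would
    stall the loop, so the draw excludes it); events falling beyond
    ``framenum`` are not emitted.
    """
    if j < 1:
        raise InvalidParameterError("j must be >= 1")
    rng = np.random.default_rng(seed)
    events: list[ActionEvent] = []
    i = 0
    while i <= framenum:
        step = int(rng.integers(1, j + 1))
        key = i + step
        if key <= framenum:
            events.append(ActionEvent(frame_key=key, pattern_id=pattern_id, **event_kw))
        i += step
    return events


def build_scenario(
    name: str,
    duration: float,
    fps: float,
    seed: int | None = None,
    gait_step: int = 12,
    blink_period_s: float = 4.0,
) -> ScenarioSpec:
    """Construct one of the four benchmark scenarios as an event timeline.

    stable
        No events; constant illumination; baseline motion gains.
    expression_talk
        Non-periodic expression/talking perturbations plus periodic blinks.
    light_change
        Non-periodically scheduled large illumination ramps (light-to-dark
        transitions and recoveries).
    physical_activity
        Periodic gait events (one per ``gait_step`` frames) and elevated
        motion gains.
    """
    if name not in SCENARIO_NAMES:
        raise InvalidParameterError(
            f"scenario must be one of {SCENARIO_NAMES}, got {name!r}"
        )
    framenum = int(round(duration * fps))
    rng = np.random.default_rng(seed)
    events: list[ActionEvent] = []
    illum_id = "constant"
    motion_scale = 1.0

    if name == "expression_talk":
        blink_step = max(1, int(round(blink_period_s * fps)))
        if framenum >= blink_step:
            events += schedule_periodic(
                framenum, blink_step, "blink",
                duration_frames=max(2, int(0.25 * fps)), magnitude=0.02,
            )
        for ev in schedule_nonperiodic(
            framenum, max(1, int(5 * fps)), "expression",
            seed=int(rng.integers(0, 2**31)),
        ):
            mag = float(rng.uniform(0.02, 0.08)) * (1 if rng.random() < 0.5 else -1)
            events.append(
                ActionEvent(ev.frame_key, "expression",
                            duration_frames=max(2, int(fps)), magnitude=mag)
            )
        illum_id = "event"
    elif name == "light_change":
        sign = -1.0  # first transition goes toward darkness
        for ev in schedule_nonperiodic(
            framenum, max(1, int(8 * fps)), "light_ramp",
            seed=int(rng.integers(0, 2**31)),
        ):
            mag = sign * float(rng.uniform(0.1, 0.4))
            sign = -sign
            events.append(
                ActionEvent(ev.frame_key, "light_ramp",
                            duration_frames=max(2, int(2 * fps)), magnitude=mag)
            )
        if not events and framenum >= 2:
            events.append(
                ActionEvent(framenum // 2, "light_ramp",
                            duration_frames=max(2, int(2 * fps)), magnitude=-0.3)
            )
        illum_id = "event"
    elif name == "physical_activity":
        if framenum >= gait_step:
            events += schedule_periodic(
                framenum, gait_step, "gait",
                duration_frames=gait_step, magnitude=0.05,
            )
        motion_scale = 3.0
        illum_id = "event"

    events.sort(key=lambda e: e.frame_key)
    return ScenarioSpec(
        name=name,
        framenum=framenum,
        events=tuple(events),
        illumination_profile_id=illum_id,
        motion_gain_scale=motion_scale,
    )


def _raised_cosine(n: int) -> np.ndarray:
    """Envelope rising from 0 to 1 and back over n frames."""
    if n == 1:
        return np.ones(1)
    k = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (n - 1)))


def scenario_modulation(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the event timeline into per-frame modulation arrays.

    Returns
    -------
    illum_factor : np.ndarray, shape (framenum,)
        Multiplicative illumination factor (1 = unperturbed, always > 0).
    motion_scale : np.ndarray, shape (framenum,)
        Multiplicative factor on the motion-intensity gains.
    """
    n = spec.framenum
    illum = np.ones(n)
    motion = np.full(n, spec.motion_gain_scale)
    for ev in spec.events:
        pat = PATTERNS[ev.pattern_id]
        start = ev.frame_key
        stop = min(n, start + ev.duration_frames)
        if stop <= start:
            continue
        env = _raised_cosine(ev.duration_frames)[: stop - start]
        if pat.illum:
            illum[start:stop] *= 1.0 + pat.illum * ev.magnitude * env
        if pat.motion_boost:
            motion[start:stop] *= 1.0 + pat.motion_boost * abs(ev.magnitude) * env
    # illumination must stay strictly positive
    np.clip(illum, 0.05, None, out=illum)
    return illum, motion
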