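"""High-level simulate / extract / evaluate plumbing."""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig, derive_seeds
from .errors import InvalidParameterError
from .evaluation import EvalReport, evaluate_waveform
from .extraction import METHODS, IPPGResult, RGBTrace, spatial_average
from .motion import (
    DEFAULT_BREATH_AMPLITUDES,
    BREATH_BAND,
    MotionGains,
    bcg_trace,
    breathing_trace,
    MotionTrace,
    project_to_intensity,
)
from .ppg import NoiseSpec, generate_beat_sequence, normalize_unit, synthesize_ppg
from .scenario import build_scenario, scenario_modulation
from .video import (
    IlluminationProfile,
    VideoCube,
    compose_frames,
    quantize,
    skin_tone_preset,
)

__all__ = ["simulate_cube", "extract_method", "evaluate_cube_result"]


def simulate_cube(config: SimulationConfig, quantize_8bit: bool = False) -> VideoCube:
    """Render one synthetic skin-patch video from a configuration.

    The master seed fans out to the beat generator, motion model, scenario
    engine and camera noise; the scenario's event timeline modulates the
    illumination and the motion gains frame by frame.
    """
    seeds = derive_seeds(config.seed)
    fps, duration = config.fps, config.duration
    n = int(round(duration * fps))
    t = np.arange(n) / fps

    # cardiac signal
    beats = generate_beat_sequence(
        config.hr, config.ibi_mod_freq, config.ibi_mod_depth, duration,
        seed=seeds["ppg"],
    )
    ppg = normalize_unit(synthesize_ppg(beats, fs=fps, duration=duration))

    # scenario timeline
    scenario = build_scenario(config.scenario, duration, fps, seed=seeds["scenario"])
    illum_factor, motion_scale = scenario_modulation(scenario)
    illum = config.illumination_I0 * illum_factor

    # involuntary motion
    motion = None
    if config.motion_enabled:
        breath_rng = np.random.default_rng(seeds["breath"])
        breath_freq = (
            config.breath_freq
            if config.breath_freq is not None
            else float(breath_rng.uniform(*BREATH_BAND))
        )
        gains = MotionGains(
            bcg=config.bcg_gain,
            head_dy=config.breath_gain,
            shoulder_dy=config.breath_gain,
            chest_dx=config.breath_gain,
        )
        bcg = bcg_trace(
            config.hr, duration, fps,
            theta_mean=config.theta_mean, theta_sd=config.theta_sd,
            seed=seeds["motion"],
        )
        breath = breathing_trace(breath_freq, duration, fps, DEFAULT_BREATH_AMPLITUDES)
        m = project_to_intensity(bcg, breath, gains) * motion_scale
        m = m - m.mean()
        motion = MotionTrace(
            t=t, bcg_angle=bcg,
            breath_head_dy=breath[0], breath_shoulder_dy=breath[1],
            breath_chest_dx=breath[2], intensity_modulation=m,
        )

    skin = skin_tone_preset(
        config.skin_tone,
        beta=tuple(config.beta),
        texture_seed=seeds["noise"],
        texture_contrast=config.texture_contrast,
    )
    noise = NoiseSpec(sigma=config.noise_sigma, seed=seeds["noise"])
    cube = compose_frames(
        skin, ppg, motion, illum, noise,
        height=config.height, width=config.width, fps=fps,
        pulse_scale=config.pulse_scale, pulse_mode=config.pulse_mode,
        ground_truth={"scenario": config.scenario, "config": config.to_dict()},
    )
    if quantize_8bit:
        cube = quantize(cube)
    return cube


def extract_method(
    source: VideoCube | RGBTrace,
    method: str,
    roi_mask: np.ndarray | None = None,
    **method_kw,
) -> IPPGResult:
    """Run one named extraction method on a video cube or RGB trace."""
    if method not in METHODS:
        raise InvalidParameterError(
            f"unknown method {method!r}; choose from {sorted(METHODS)}"
        )
    trace = (
        spatial_average(source, roi_mask) if isinstance(source, VideoCube) else source
    )
    return METHODS[method](trace, **method_kw)


def evaluate_cube_result(
    cube: VideoCube, result: IPPGResult, window_s: float = 10.0
) -> EvalReport:
    """Score a recovered waveform against the cube's ground-truth HR trace."""
    truth = np.asarray(cube.ground_truth["hr_trace"], dtype=float)
    return evaluate_waveform(
        result.waveform, cube.fps, truth,
        window_s=window_s,
        method_id=result.method_id,
        scenario_id=str(cube.ground_truth.get("scenario", "")),
    )
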