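"""Readers and writers: lossless PNG frame sequences, .npz float cubes,
CSV traces and JSON/YAML sidecars.

PNG frame sequences are the default on-disk video format because they are
lossless; lossy codecs destroy the sub-percent pulsatile signal.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import InvalidParameterError
from .video import VideoCube, quantize

__all__ = [
    "write_cube",
    "read_cube",
    "write_trace_csv",
    "read_trace_csv",
    "write_motion_csv",
]

_FRAME_PATTERN = "frame_{:05d}.png"
_GT_FILE = "ground_truth.json"
_CONFIG_FILE = "config.yaml"
_FLOAT_FILE = "frames.npz"


def _gt_to_json(gt: dict) -> dict:
    out = {}
    for k, v in gt.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


def write_cube(
    cube: VideoCube,
    out_dir: str | Path,
    config: SimulationConfig | None = None,
    keep_float: bool = False,
) -> Path:
    """Write a video cube as a PNG frame sequence with sidecar ground truth.

    Float cubes are quantized to 8-bit PNGs; ``keep_float`` additionally
    stores the exact float frames in a compressed .npz container.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    q = cube if cube.bit_depth == "uint8" else quantize(cube)
    for i in range(q.n_frames):
        iio.imwrite(out / _FRAME_PATTERN.format(i), q.frames[i])
    if keep_float and cube.bit_depth == "float32":
        np.savez_compressed(out / _FLOAT_FILE, frames=cube.frames, fps=cube.fps)
    meta = _gt_to_json(cube.ground_truth)
    meta["fps"] = cube.fps
    meta["n_frames"] = q.n_frames
    (out / _GT_FILE).write_text(json.dumps(meta))
    if config is not None:
        (out / _CONFIG_FILE).write_text(config.to_yaml())
    return out


def read_cube(in_dir: str | Path, prefer_float: bool = True) -> VideoCube:
    """Load a cube written by :func:`write_cube` (or any PNG frame dir)."""
    src = Path(in_dir)
    gt: dict = {}
    fps = 25.0
    gt_path = src / _GT_FILE
    if gt_path.exists():
        meta = json.loads(gt_path.read_text())
        fps = float(meta.pop("fps", fps))
        meta.pop("n_frames", None)
        gt = {
            k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
            for k, v in meta.items()
        }
    float_path = src / _FLOAT_FILE
    if prefer_float and float_path.exists():
        with np.load(float_path) as z:
            return VideoCube(
                frames=z["frames"], fps=float(z["fps"]),
                bit_depth="float32", ground_truth=gt,
            )
    frame_files = sorted(src.glob("frame_*.png")) or sorted(src.glob("*.png"))
    if not frame_files:
        raise InvalidParameterError(f"no PNG frames found in {src}")
    frames = np.stack([iio.imread(f) for f in frame_files])
    if frames.ndim == 3:  # grayscale fallback: replicate channels
        frames = np.repeat(frames[..., None], 3, axis=-1)
    return VideoCube(frames=frames, fps=fps, bit_depth="uint8", ground_truth=gt)


def write_trace_csv(path: str | Path, t: np.ndarray, value: np.ndarray, value_name: str = "value") -> Path:
    """Serialize a 1-D waveform as a (time_s, value) CSV."""
    path = Path(path)
    pd.DataFrame({"time_s": np.asarray(t), value_name: np.asarray(value)}).to_csv(
        path, index=False
    )
    return path


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_motion_csv(path: str | Path, motion) -> Path:
    """Export a MotionTrace beside its video."""
    path = Path(path)
    pd.DataFrame({
        "time_s": motion.t,
        "bcg_deg": motion.bcg_angle,
        "head_dy": motion.breath_head_dy,
        "shoulder_dy": motion.breath_shoulder_dy,
        "chest_dx": motion.breath_chest_dx,
        "m": motion.intensity_modulation,
    }).to_csv(path, index=False)
    return path
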