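"""Block-wise application of a trained network and physical-unit conversion.

Long sequences are processed as non-overlapping fixed-length blocks with the
recurrent state reset between blocks; outputs are converted from pixel-space
(pixels/frame, scaled angle) into mm/s and radians, temporally accumulated,
and reduced to ROI pulsatility traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from smv.image_synth import FrameSequence, VelocityMap, unscale_angle

__all__ = [
    "VelocimetryResult",
    "infer_blocks",
    "to_physical",
    "accumulate",
    "roi_trace",
    "split_events",
]

#: default flow-event threshold (px/frame)
EVENT_EPS = 0.05


@dataclass
class VelocimetryResult:
    maps: list[VelocityMap] = field(default_factory=list)
    pixel_size: float = 4.9  # um
    frame_interval: float = 1.0  # ms
    block_len: int = 16

    def __post_init__(self):
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("calibration must be positive")

    def __len__(self):
        return len(self.maps)


def infer_blocks(frames: FrameSequence, model, block_len: int = 16) -> VelocimetryResult:
    """Run the model on consecutive non-overlapping blocks.

    The LSTM state is implicitly reset per block (each forward starts from a
    zero state). Inputs are normalized per block by the block max; spatial
    sizes not divisible by the model stride are reflect-padded and the output
    cropped back. A trailing remainder shorter than ``block_len`` is dropped
    with a warning.
    """
    t = frames.frames.shape[0]
    if t < block_len:
        raise ValueError(f"need at least {block_len} frames, got {t}")
    n_blocks = t // block_len
    if t % block_len:
        warnings.warn(
            f"dropping trailing {t % block_len} frames (< block_len)", stacklevel=2
        )
    stride = 2 ** model.cfg.depth
    model.train(False)
    maps = []
    for b in range(n_blocks):
        block = frames.frames[b * block_len : (b + 1) * block_len].astype(np.float32)
        peak = block.max()
        if peak > 0:
            block = block / peak
        padded, crop = _pad_to_multiple(block, stride)
        pred = model.forward(padded[:, None])  # (2, H', W')
        pred = pred[:, crop[0] : crop[0] + block.shape[1], crop[1] : crop[1] + block.shape[2]]
        maps.append(VelocityMap(magnitude=np.maximum(pred[0], 0.0), angle=pred[1]))
    return VelocimetryResult(
        maps=maps,
        pixel_size=frames.pixel_size,
        frame_interval=frames.frame_interval,
        block_len=block_len,
    )


def _pad_to_multiple(block: np.ndarray, stride: int):
    t, h, w = block.shape
    ph = (-h) % stride
    pw = (-w) % stride
    if ph == 0 and pw == 0:
        return block, (0, 0)
    top, left = ph // 2, pw // 2
    padded = np.pad(block, ((0, 0), (top, ph - top), (left, pw - left)), mode="reflect")
    return padded, (top, left)


def to_physical(vmap: VelocityMap, pixel_size: float = 4.9, frame_interval: float = 1.0):
    """(magnitude px/frame, scaled angle) -> (mm/s, radians in [-pi, pi]).

    v[mm/s] = magnitude * pixel_size[um] / frame_interval[ms]. Positive axial
    velocity component (negative image-row direction) means flow toward the
    transducer.
    """
    if pixel_size <= 0 or frame_interval <= 0:
        raise ValueError("calibration must be positive")
    speed = vmap.magnitude * pixel_size / frame_interval
    theta = unscale_angle(vmap.angle)
    return speed, theta


def accumulate(result: VelocimetryResult, min_magnitude: float = EVENT_EPS) -> VelocityMap:
    """Per-pixel mean magnitude over blocks where magnitude exceeds epsilon.

    Angle is the circular mean of the contributing blocks' angles. Pixels
    never above threshold are zero.
    """
    if len(result) == 0:
        raise ValueError("no maps to accumulate")
    mags = np.stack([m.magnitude for m in result.maps])
    angs = np.stack([m.angle for m in result.maps])
    active = mags > min_magnitude
    count = active.sum(axis=0)
    mag_sum = np.where(active, mags, 0.0).sum(axis=0)
    mean_mag = np.divide(mag_sum, count, out=np.zeros_like(mag_sum), where=count > 0)
    theta = unscale_angle(angs)
    sin_sum = np.where(active, np.sin(theta), 0.0).sum(axis=0)
    cos_sum = np.where(active, np.cos(theta), 0.0).sum(axis=0)
    mean_theta = np.arctan2(sin_sum, cos_sum)
    angle = np.where(count > 0, (mean_theta + np.pi) / (2 * np.pi), 0.0)
    return VelocityMap(magnitude=mean_mag, angle=angle)


def roi_trace(
    result: VelocimetryResult, roi_mask: np.ndarray, min_magnitude: float = EVENT_EPS
) -> np.ndarray:
    """Per-block mean physical magnitude (mm/s) over ROI pixels above epsilon."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if len(result) == 0:
        raise ValueError("empty result")
    if roi_mask.shape != result.maps[0].magnitude.shape:
        raise ValueError("ROI shape mismatch")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    scale = result.pixel_size / result.frame_interval
    trace = np.zeros(len(result))
    for i, m in enumerate(result.maps):
        vals = m.magnitude[roi_mask]
        vals = vals[vals > min_magnitude]
        trace[i] = vals.mean() * scale if vals.size else 0.0
    return trace


def split_events(
    result: VelocimetryResult, min_magnitude: float = EVENT_EPS
) -> tuple[VelocityMap, VelocityMap]:
    """Accumulate even- and odd-indexed blocks into two independent maps.

    Each half is normalized by its own per-pixel flow-event counts (pixels
    with magnitude above epsilon), mirroring event-normalized accumulation.
    """
    if len(result) < 2:
        raise ValueError("need at least two maps to split")
    halves = []
    for parity in (0, 1):
        sub = VelocimetryResult(
            maps=result.maps[parity::2],
            pixel_size=result.pixel_size,
            frame_interval=result.frame_interval,
            block_len=result.block_len,
        )
        halves.append(accumulate(sub, min_magnitude))
    return halves[0], halves[1]
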