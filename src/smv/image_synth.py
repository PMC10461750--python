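"""Frame rendering and ground-truth rasterization.

Turns microbubble flow records into diffraction-limited magnitude sequences by
splatting PSF patches at sub-pixel bubble positions (with per-frame jitter in
rotation/scale and Rayleigh electronic noise), and rasterizes dense
two-channel (magnitude, scaled angle) velocity maps from annotated graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import match_template, peak_local_max

from smv.flow_sim import FlowRecord, SimConfig, simulate
from smv.vessel_graph import (
    RadiusVelocityTable,
    VesselGraph,
    VesselMask,
    assign_reference_velocity,
    build_undirected_graph,
    orient_graph,
    skeletonize_mask,
)

__all__ = [
    "PSFBank",
    "FrameSequence",
    "VelocityMap",
    "gaussian_psf",
    "extract_psf_bank",
    "render_sequence",
    "add_noise",
    "rasterize_ground_truth",
    "make_training_set",
    "scale_angle",
    "unscale_angle",
    "save_dataset_hdf5",
    "load_dataset_hdf5",
]


@dataclass
class PSFBank:
    """Peak-normalized odd-sized PSF patches."""

    patches: list[np.ndarray]
    pixel_size: float = 4.9

    def __post_init__(self) -> None:
        norm = []
        for p in self.patches:
            p = np.asarray(p, dtype=float)
            if p.ndim != 2 or p.shape[0] % 2 == 0 or p.shape[1] % 2 == 0:
                raise ValueError("PSF patches must be 2-D with odd dimensions")
            peak = p.max()
            if peak <= 0:
                raise ValueError("PSF patch must have a positive peak")
            norm.append(p / peak)
        self.patches = norm

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class FrameSequence:
    """T x H x W non-negative magnitude frames with calibration."""

    frames: np.ndarray
    pixel_size: float = 4.9  # um
    frame_interval: float = 1.0  # ms

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames must be finite")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("calibration must be positive")

    @property
    def shape(self):
        return self.frames.shape


@dataclass
class VelocityMap:
    """Two-channel ground truth / prediction.

    magnitude in pixels/ms (== pixels/frame at 1 kHz framing); angle is the
    flow direction scaled from [-pi, pi] to [0, 1].
    """

    magnitude: np.ndarray
    angle: np.ndarray

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.magnitude.shape != self.angle.shape:
            raise ValueError("magnitude/angle shape mismatch")

    def as_array(self) -> np.ndarray:
        return np.stack([self.magnitude, self.angle])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "VelocityMap":
        return cls(magnitude=arr[0], angle=arr[1])


def scale_angle(theta: np.ndarray) -> np.ndarray:
    """Map angle in [-pi, pi] to [0, 1]."""
    return (np.asarray(theta, dtype=float) + np.pi) / (2.0 * np.pi)


def unscale_angle(a: np.ndarray) -> np.ndarray:
    """Inverse of :func:`scale_angle`."""
    return 2.0 * np.pi * np.asarray(a, dtype=float) - np.pi


def gaussian_psf(sigma_ax: float = 4.0, sigma_lat: float = 6.0, size: int = 25) -> np.ndarray:
    """Anisotropic Gaussian patch, peak 1 at the centre.

    Rows are the axial direction (sigma_ax), columns lateral (sigma_lat).
    """
    if sigma_ax <= 0 or sigma_lat <= 0:
        raise ValueError("sigmas must be positive")
    if size % 2 == 0:
        raise ValueError("size must be odd")
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    return np.exp(-0.5 * ((y / sigma_ax) ** 2 + (x / sigma_lat) ** 2))


def extract_psf_bank(
    frames: FrameSequence,
    template: np.ndarray,
    corr_threshold: float = 0.8,
    max_patches: int = 200,
) -> PSFBank:
    """Harvest PSF patches from frames of isolated bubbles.

    Normalized cross-correlation against ``template``; local maxima above
    ``corr_threshold`` are cut out at the template size and peak-normalized.
    """
    th, tw = template.shape
    patches = []
    for frame in frames.frames:
        if frame.max() <= 0:
            continue
        ncc = match_template(frame, template, pad_input=True)
        peaks = peak_local_max(
            ncc, min_distance=max(th, tw) // 2, threshold_abs=corr_threshold
        )
        for r, c in peaks:
            r0, c0 = r - th // 2, c - tw // 2
            if r0 < 0 or c0 < 0 or r0 + th > frame.shape[0] or c0 + tw > frame.shape[1]:
                continue
            patch = frame[r0 : r0 + th, c0 : c0 + tw]
            if patch.max() > 0:
                patches.append(patch.copy())
            if len(patches) >= max_patches:
                break
        if len(patches) >= max_patches:
            break
    if not patches:
        raise ValueError(
            "no PSF candidates found; lower corr_threshold or check the frames"
        )
    return PSFBank(patches=patches, pixel_size=frames.pixel_size)


@dataclass
class RenderConfig:
    rotation_deg: float = 5.0  # max |rotation| per frame
    scale_jitter: float = 0.05  # max anisotropic scale deviation per frame
    noise_sigma: float = 0.0  # Rayleigh scale, relative to clip max when > 0
    rng_seed: int = 0


def render_sequence(
    record: FlowRecord,
    bank_or_patch,
    grid: tuple[int, int] | None = None,
    cfg: RenderConfig | None = None,
) -> FrameSequence:
    """Render a flow record into magnitude frames by PSF splatting.

    Each bubble is assigned one bank patch at birth and keeps it for its
    lifetime; per frame, the patch receives a small random rotation and
    anisotropic scaling, is scaled by the bubble amplitude, and is added at
    the sub-pixel bubble position with bilinear weighting.
    """
    cfg = cfg or RenderConfig()
    if grid is None:
        grid = record.shape
    h, w = grid
    if isinstance(bank_or_patch, PSFBank):
        bank = bank_or_patch
    else:
        bank = PSFBank(patches=[np.asarray(bank_or_patch, dtype=float)])
    rng = np.random.default_rng(cfg.rng_seed)
    patch_of: dict[int, int] = {}
    frames = np.zeros((len(record.frames), h, w))
    clipped = False
    for t, fr in enumerate(record.frames):
        for i in range(len(fr.amplitudes)):
            mb_id = int(fr.mb_ids[i])
            if mb_id not in patch_of:
                patch_of[mb_id] = int(rng.integers(len(bank)))
            patch = bank.patches[patch_of[mb_id]]
            if cfg.rotation_deg > 0 or cfg.scale_jitter > 0:
                patch = _distort(patch, rng, cfg.rotation_deg, cfg.scale_jitter)
            pos = fr.positions[i]
            if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                clipped = True
            _splat(frames[t], patch, pos, fr.amplitudes[i])
    if clipped:
        warnings.warn("some bubble positions fell outside the grid and were clipped", stacklevel=2)
    return FrameSequence(frames=frames, pixel_size=bank.pixel_size)


def _distort(patch, rng, rot_deg, scale_jitter):
    ang = rng.uniform(-rot_deg, rot_deg)
    sy = 1.0 + rng.uniform(-scale_jitter, scale_jitter)
    sx = 1.0 + rng.uniform(-scale_jitter, scale_jitter)
    out = ndimage.rotate(patch, ang, reshape=False, order=1, mode="constant")
    out = ndimage.zoom(out, (sy, sx), order=1, mode="constant")
    # re-centre to odd shape
    return _crop_or_pad_odd(out, patch.shape)


def _crop_or_pad_odd(arr, shape):
    th, tw = shape
    h, w = arr.shape
    out = np.zeros(shape)
    r0 = (h - th) // 2
    c0 = (w - tw) // 2
    rs = slice(max(0, r0), max(0, r0) + min(h, th))
    cs = slice(max(0, c0), max(0, c0) + min(w, tw))
    ro = slice(max(0, -r0), max(0, -r0) + min(h, th))
    co = slice(max(0, -c0), max(0, -c0) + min(w, tw))
    out[ro, co] = arr[rs, cs]
    return out


def _splat(frame: np.ndarray, patch: np.ndarray, pos: np.ndarray, amp: float) -> None:
    """Add ``amp * patch`` centred at sub-pixel ``pos`` via bilinear weights."""
    h, w = frame.shape
    ph, pw = patch.shape
    r0f = pos[0] - ph // 2
    c0f = pos[1] - pw // 2
    ri, ci = int(np.floor(r0f)), int(np.floor(c0f))
    fr_, fc = r0f - ri, c0f - ci
    weights = [
        (ri, ci, (1 - fr_) * (1 - fc)),
        (ri + 1, ci, fr_ * (1 - fc)),
        (ri, ci + 1, (1 - fr_) * fc),
        (ri + 1, ci + 1, fr_ * fc),
    ]
    for rr, cc, wgt in weights:
        if wgt == 0.0:
            continue
        r_lo, r_hi = max(0, rr), min(h, rr + ph)
        c_lo, c_hi = max(0, cc), min(w, cc + pw)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        frame[r_lo:r_hi, c_lo:c_hi] += (
            amp * wgt * patch[r_lo - rr : r_hi - rr, c_lo - cc : c_hi - cc]
        )


def add_noise(frames: FrameSequence, sigma: float, rng_seed: int = 0) -> FrameSequence:
    """Add Rayleigh noise |N(0,s^2) + i N(0,s^2)| per pixel (electronic noise)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return FrameSequence(
            frames=frames.frames.copy(),
            pixel_size=frames.pixel_size,
            frame_interval=frames.frame_interval,
        )
    rng = np.random.default_rng(rng_seed)
    re = rng.normal(0.0, sigma, frames.frames.shape)
    im = rng.normal(0.0, sigma, frames.frames.shape)
    return FrameSequence(
        frames=frames.frames + np.hypot(re, im),
        pixel_size=frames.pixel_size,
        frame_interval=frames.frame_interval,
    )


def rasterize_ground_truth(
    g: VesselGraph, grid: tuple[int, int] | None = None, profile_exponent: int = 1
) -> VelocityMap:
    """Dense two-channel ground truth from an annotated graph.

    Pixels within the local radius of an edge centerline get magnitude
    v_ref * (1 - (d/r)**p) and the scaled local tangent angle; where vessels
    overlap, the larger magnitude wins.
    """
    grid = tuple(grid) if grid is not None else tuple(g.shape)
    mag = np.zeros(grid)
    ang = np.zeros(grid)
    for e in g.edges:
        if len(e.path) == 0:
            continue
        pts = e.path.astype(float)
        radii = e.radii
        tangents = _path_tangents(pts)
        rmax = float(radii.max())
        r_lo = max(0, int(np.floor(pts[:, 0].min() - rmax - 1)))
        r_hi = min(grid[0], int(np.ceil(pts[:, 0].max() + rmax + 2)))
        c_lo = max(0, int(np.floor(pts[:, 1].min() - rmax - 1)))
        c_hi = min(grid[1], int(np.ceil(pts[:, 1].max() + rmax + 2)))
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        tree = cKDTree(pts)
        dist, idx = tree.query(pix)
        r_at = radii[idx]
        inside = dist <= r_at
        if not inside.any():
            continue
        prof = e.v_ref * (1.0 - (dist[inside] / r_at[inside]) ** profile_exponent)
        t_in = tangents[idx[inside]]
        theta = np.arctan2(t_in[:, 0], t_in[:, 1])
        sub_r = pix[inside, 0].astype(int)
        sub_c = pix[inside, 1].astype(int)
        cur = mag[sub_r, sub_c]
        win = prof > cur
        mag[sub_r[win], sub_c[win]] = prof[win]
        ang[sub_r[win], sub_c[win]] = scale_angle(theta[win])
    return VelocityMap(magnitude=mag, angle=ang)


def _path_tangents(pts: np.ndarray) -> np.ndarray:
    if len(pts) == 1:
        return np.array([[0.0, 1.0]])
    diffs = np.gradient(pts, axis=0)
    norms = np.hypot(diffs[:, 0], diffs[:, 1])
    norms[norms == 0] = 1.0
    return diffs / norms[:, None]


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


@dataclass
class DatasetConfig:
    clip_len: int = 16
    patch: int = 256
    n_bubbles: int = 60
    noise_sigma_rel: float = 0.1  # Rayleigh scale relative to clip max
    profile_exponent: int = 1
    pixel_size: float = 4.9
    frame_interval: float = 1.0
    validation_fraction: float = 0.1
    velocity_table: RadiusVelocityTable | None = None
    #: optional callable mask -> velocity map, switches to per-segment
    #: assignment from the map instead of table draws
    velocity_map_fn: object = None


def make_training_set(
    templates: list[VesselMask],
    n_samples: int,
    cfg: DatasetConfig | None = None,
    bank: PSFBank | None = None,
    rng_seed: int = 0,
):
    """Generate (input clip, target map) pairs from vascular templates.

    Per sample: choose a template, build+orient its graph, assign velocities,
    simulate ``clip_len`` steps, render, add noise, normalize by the clip max,
    and rasterize the ground-truth velocity map. Returns
    (inputs [n, T, P, P] float32, targets [n, 2, P, P] float32, split index).
    """
    if not templates:
        raise ValueError("need at least one template")
    cfg = cfg or DatasetConfig()
    rng = np.random.default_rng(rng_seed)
    if bank is None:
        bank = PSFBank(patches=[gaussian_psf()], pixel_size=cfg.pixel_size)
    table = cfg.velocity_table or _default_velocity_table()

    inputs = np.zeros((n_samples, cfg.clip_len, cfg.patch, cfg.patch), dtype=np.float32)
    targets = np.zeros((n_samples, 2, cfg.patch, cfg.patch), dtype=np.float32)
    for i in range(n_samples):
        mask = templates[int(rng.integers(len(templates)))]
        g = orient_graph(build_undirected_graph(skeletonize_mask(mask)))
        if cfg.velocity_map_fn is not None:
            from smv.vessel_graph import assign_velocity_from_map

            assign_velocity_from_map(g, cfg.velocity_map_fn(mask), fallback_table=table)
        else:
            assign_reference_velocity(g, table, rng_seed=rng)
        sim_cfg = SimConfig(
            N=cfg.n_bubbles,
            dt=cfg.frame_interval,
            T=cfg.clip_len,
            rng_seed=int(rng.integers(2**31)),
        )
        record = simulate(g, sim_cfg)
        rcfg = RenderConfig(rng_seed=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            # border vessels legitimately push a few bubbles off-grid
            warnings.simplefilter("ignore", UserWarning)
            seq = render_sequence(record, bank, grid=(cfg.patch, cfg.patch), cfg=rcfg)
        peak = seq.frames.max()
        if cfg.noise_sigma_rel > 0 and peak > 0:
            seq = add_noise(seq, cfg.noise_sigma_rel * peak, rng_seed=int(rng.integers(2**31)))
        peak = seq.frames.max()
        clip = seq.frames / peak if peak > 0 else seq.frames
        gt = rasterize_ground_truth(g, grid=(cfg.patch, cfg.patch), profile_exponent=cfg.profile_exponent)
        inputs[i] = clip.astype(np.float32)
        targets[i] = gt.as_array().astype(np.float32)
    n_val = int(round(n_samples * cfg.validation_fraction))
    split = n_samples - n_val
    return inputs, targets, split


def _default_velocity_table() -> RadiusVelocityTable:
    """Synthetic radius->velocity prior: speed grows with vessel radius."""
    radii = np.linspace(0.5, 12.0, 64)
    vels = 0.4 * radii  # px/frame, ~0.2..4.8 over typical radii
    return RadiusVelocityTable(pairs=np.column_stack([radii, vels]))


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------


def save_dataset_hdf5(path, inputs, targets, split, pixel_size=4.9, frame_interval=1.0, seed=0):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("inputs", data=inputs)
        fh.create_dataset("targets", data=targets)
        fh.attrs["split"] = split
        fh.attrs["pixel_size"] = pixel_size
        fh.attrs["frame_interval"] = frame_interval
        fh.attrs["seed"] = seed


def load_dataset_hdf5(path):
    with h5py.File(path, "r") as fh:
        return (
            fh["inputs"][()],
            fh["targets"][()],
            int(fh.attrs["split"]),
            dict(fh.attrs),
        )
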