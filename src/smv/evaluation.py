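"""Quantitative assessment of velocity reconstructions.

Velocity RMSE (pixel and physical units), vessel-profile FWHM, Fourier ring
correlation resolution with half-bit and 2-sigma criteria, and
mass-conservation reference velocities for flow-channel validation.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from smv.image_synth import VelocityMap

__all__ = [
    "velocity_rmse",
    "fwhm",
    "frc_curve",
    "frc_resolution",
    "channel_reference_velocity",
    "bias_table",
    "UNRESOLVED",
]

#: sentinel returned when the FRC never crosses its threshold curve
UNRESOLVED = float("inf")


def velocity_rmse(
    pred: VelocityMap,
    truth: VelocityMap,
    mask_mode: str = "vessel",
    pixel_size: float = 4.9,
    frame_interval: float = 1.0,
) -> tuple[float, float]:
    """RMSE of the magnitude channel, in (px/frame, mm/s).

    ``mask_mode='vessel'`` restricts to pixels where the truth magnitude is
    positive; ``'all'`` uses every pixel.
    """
    if pred.magnitude.shape != truth.magnitude.shape:
        raise ValueError("shape mismatch")
    if mask_mode == "vessel":
        sel = truth.magnitude > 0
        if not sel.any():
            raise ValueError("empty vessel mask in truth map")
    elif mask_mode == "all":
        sel = np.ones_like(truth.magnitude, dtype=bool)
    else:
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    err = pred.magnitude[sel] - truth.magnitude[sel]
    rmse_px = float(np.sqrt(np.mean(err**2)))
    return rmse_px, rmse_px * pixel_size / frame_interval


def fwhm(profile: np.ndarray, pixel_size: float = 4.9) -> float:
    """Full width at half maximum of a single-peaked 1-D profile, in um.

    The two half-maximum crossings are located by linear interpolation around
    the dominant peak.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or len(profile) < 3:
        raise ValueError("need a 1-D profile with >= 3 samples")
    peak_idx = int(np.argmax(profile))
    peak = profile[peak_idx]
    base = profile.min()
    half = base + 0.5 * (peak - base)
    left = _crossing(profile, peak_idx, half, direction=-1)
    right = _crossing(profile, peak_idx, half, direction=+1)
    if left is None or right is None:
        raise ValueError("profile does not cross half maximum on both sides")
    return (right - left) * pixel_size


def _crossing(profile, peak_idx, half, direction):
    i = peak_idx
    while 0 <= i + direction < len(profile):
        j = i + direction
        if profile[j] <= half:
            # linear interpolation between i and j
            if profile[i] == profile[j]:
                return float(j)
            frac = (profile[i] - half) / (profile[i] - profile[j])
            return i + direction * frac
        i = j
    return None


def frc_curve(map1: np.ndarray, map2: np.ndarray):
    """Fourier ring correlation over 1-px-wide rings.

    Returns (spatial frequencies in cycles/px, FRC values, ring sample counts).
    """
    a = np.asarray(map1, dtype=float)
    b = np.asarray(map2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))
    h, w = a.shape
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    # radius normalized so ring k corresponds to frequency k / size
    r = np.hypot((yy - cy) / h, (xx - cx) / w)
    n_rings = min(cy, cx)
    ring = np.minimum((r * min(h, w)).astype(int), n_rings)
    cross = np.real(fa * np.conj(fb))
    p1 = np.abs(fa) ** 2
    p2 = np.abs(fb) ** 2
    num = np.bincount(ring.ravel(), cross.ravel(), minlength=n_rings + 1)[:n_rings]
    d1 = np.bincount(ring.ravel(), p1.ravel(), minlength=n_rings + 1)[:n_rings]
    d2 = np.bincount(ring.ravel(), p2.ravel(), minlength=n_rings + 1)[:n_rings]
    counts = np.bincount(ring.ravel(), minlength=n_rings + 1)[:n_rings]
    denom = np.sqrt(d1 * d2)
    frc = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    freqs = np.arange(n_rings) / min(h, w)  # cycles per pixel
    return freqs, frc, counts


def half_bit_threshold(counts: np.ndarray) -> np.ndarray:
    """Standard half-bit information threshold curve."""
    n = np.sqrt(np.maximum(counts, 1) / 2.0)
    return (0.2071 + 1.9102 / n) / (1.2071 + 0.9102 / n)


def two_sigma_threshold(counts: np.ndarray) -> np.ndarray:
    """2-sigma significance curve from per-ring sample counts."""
    return 2.0 / np.sqrt(np.maximum(counts, 1) / 2.0)


def frc_resolution(
    map1: np.ndarray,
    map2: np.ndarray,
    pixel_size: float = 4.9,
    criterion: str = "half_bit",
) -> float:
    """Resolution (um) at the first FRC crossing below the threshold curve.

    Returns the UNRESOLVED sentinel (inf) when no crossing occurs.
    """
    freqs, frc, counts = frc_curve(map1, map2)
    if criterion == "half_bit":
        thresh = half_bit_threshold(counts)
    elif criterion == "two_sigma":
        thresh = two_sigma_threshold(counts)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    below = frc[1:] < thresh[1:]  # skip the DC ring
    if not below.any():
        return UNRESOLVED
    k = int(np.argmax(below)) + 1
    f = freqs[k]
    if f <= 0:
        return UNRESOLVED
    return pixel_size / f


def channel_reference_velocity(volume_rate: float, diameter: float) -> tuple[float, float]:
    """Mass-conservation reference velocities for a cylindrical channel.

    ``volume_rate`` in uL/min, ``diameter`` in um. Returns (mean, peak) in
    mm/s; peak = 2 * mean for a parabolic profile.
    """
    if volume_rate < 0 or diameter <= 0:
        raise ValueError("inputs must be positive (volume_rate may be 0)")
    q = volume_rate / 60.0  # uL/min -> mm^3/s
    radius_mm = diameter / 2.0 / 1000.0
    v_mean = q / (np.pi * radius_mm**2)
    return float(v_mean), float(2.0 * v_mean)


def bias_table(
    estimates: dict[float, float], references: dict[float, float]
) -> pd.DataFrame:
    """Per-volume-rate estimated vs reference velocity with relative bias."""
    rows = []
    for rate in sorted(references):
        if rate not in estimates:
            raise KeyError(f"missing estimate for volume rate {rate}")
        est, ref = estimates[rate], references[rate]
        bias = (est - ref) / ref * 100.0 if ref != 0 else np.nan
        rows.append({"volume_rate": rate, "estimate": est, "reference": ref, "bias_pct": bias})
    return pd.DataFrame(rows)


def metrics_to_csv(df: pd.DataFrame, path: str, meta: dict | None = None) -> None:
    """CSV with a JSON metadata header line (# prefixed)."""
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta or {}) + "\n")
        df.to_csv(fh, index=False)
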