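"""Simplified conventional localization-and-tracking velocimetry.

Serves as an independent oracle on sparse simulations and as the comparison
arm: NCC localization with sub-pixel refinement, greedy nearest-neighbour
frame-to-frame linking (optional constant-velocity Kalman prediction), and
track splatting into a velocity map.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _line
from skimage.feature import match_template, peak_local_max

from smv.image_synth import FrameSequence, VelocityMap, scale_angle

__all__ = [
    "Localization",
    "Track",
    "localize",
    "localize_sequence",
    "link_tracks",
    "tracks_to_map",
    "tracks_to_csv",
]


@dataclass
class Localization:
    frame: int
    row: float
    col: float
    score: float


@dataclass
class Track:
    localizations: list[Localization] = field(default_factory=list)

    @property
    def velocities(self) -> np.ndarray:
        """Per-step (v_row, v_col) in px/frame."""
        pts = np.array([[lo.row, lo.col] for lo in self.localizations])
        return np.diff(pts, axis=0)

    def __len__(self):
        return len(self.localizations)


def localize(
    frame: np.ndarray,
    psf: np.ndarray,
    corr_threshold: float = 0.6,
    min_separation: float | None = None,
    frame_index: int = 0,
) -> list[Localization]:
    """NCC against the PSF, thresholded local maxima, centroid refinement.

    Sub-pixel positions come from a 3x3 intensity-weighted centroid on the
    correlation map around each peak.
    """
    frame = np.asarray(frame, dtype=float)
    if psf.shape[0] >= frame.shape[0] or psf.shape[1] >= frame.shape[1]:
        raise ValueError("PSF patch must be smaller than the frame")
    if min_separation is None:
        min_separation = _fwhm_px(psf)
    if frame.max() <= 0:
        return []
    ncc = match_template(frame, psf, pad_input=True)
    peaks = peak_local_max(
        ncc, min_distance=max(1, int(round(min_separation))), threshold_abs=corr_threshold
    )
    out = []
    for r, c in peaks:
        dr, dc = _centroid_offset(ncc, r, c)
        out.append(Localization(frame=frame_index, row=r + dr, col=c + dc, score=float(ncc[r, c])))
    return out


def _fwhm_px(psf: np.ndarray) -> float:
    """Rough FWHM of the PSF peak, used as the default NMS separation."""
    prof = psf[psf.shape[0] // 2]
    above = prof >= 0.5 * prof.max()
    return float(max(above.sum(), 1))


def _centroid_offset(ncc: np.ndarray, r: int, c: int) -> tuple[float, float]:
    r0, r1 = max(0, r - 1), min(ncc.shape[0], r + 2)
    c0, c1 = max(0, c - 1), min(ncc.shape[1], c + 2)
    win = ncc[r0:r1, c0:c1].copy()
    win -= win.min()
    total = win.sum()
    if total <= 0:
        return 0.0, 0.0
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return float((win * yy).sum() / total - r), float((win * xx).sum() / total - c)


def localize_sequence(
    frames: FrameSequence, psf: np.ndarray, corr_threshold: float = 0.6,
    min_separation: float | None = None,
) -> list[list[Localization]]:
    return [
        localize(f, psf, corr_threshold, min_separation, frame_index=t)
        for t, f in enumerate(frames.frames)
    ]


def link_tracks(
    localizations: list[list[Localization]],
    max_disp: float = 10.0,
    min_track_len: int = 4,
    kalman: bool = False,
) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame assignment within ``max_disp``.

    With ``kalman`` enabled, candidate matching uses a constant-velocity
    prediction of each track's next position instead of its last position.
    Tracks shorter than ``min_track_len`` are discarded.
    """
    open_tracks: list[Track] = []
    done: list[Track] = []
    for frame_locs in localizations:
        unmatched = list(frame_locs)
        # build candidate pairs (distance, track, loc)
        pairs = []
        for tr in open_tracks:
            pr, pc = _predict(tr, kalman)
            for lo in unmatched:
                d = np.hypot(lo.row - pr, lo.col - pc)
                if d <= max_disp:
                    pairs.append((d, tr, lo))
        pairs.sort(key=lambda p: p[0])
        used_tracks, used_locs = set(), set()
        next_open = []
        for d, tr, lo in pairs:
            if id(tr) in used_tracks or id(lo) in used_locs:
                continue
            tr.localizations.append(lo)
            used_tracks.add(id(tr))
            used_locs.add(id(lo))
        for tr in open_tracks:
            if id(tr) in used_tracks:
                next_open.append(tr)
            else:
                done.append(tr)
        for lo in unmatched:
            if id(lo) not in used_locs:
                next_open.append(Track(localizations=[lo]))
        open_tracks = next_open
    done.extend(open_tracks)
    return [t for t in done if len(t) >= min_track_len]


def _predict(tr: Track, kalman: bool) -> tuple[float, float]:
    last = tr.localizations[-1]
    if kalman and len(tr) >= 2:
        prev = tr.localizations[-2]
        return 2 * last.row - prev.row, 2 * last.col - prev.col
    return last.row, last.col


def tracks_to_map(tracks: list[Track], grid: tuple[int, int]) -> VelocityMap:
    """Splat per-step speeds along each track segment; overlaps average."""
    h, w = grid
    acc = np.zeros(grid)
    ang_sin = np.zeros(grid)
    ang_cos = np.zeros(grid)
    count = np.zeros(grid)
    for tr in tracks:
        pts = np.array([[lo.row, lo.col] for lo in tr.localizations])
        vels = tr.velocities
        for i in range(len(vels)):
            speed = float(np.hypot(*vels[i]))
            theta = float(np.arctan2(vels[i][0], vels[i][1]))
            r0, c0 = np.round(pts[i]).astype(int)
            r1, c1 = np.round(pts[i + 1]).astype(int)
            rr, cc = _line(r0, c0, r1, c1)
            if i < len(vels) - 1 and len(rr) > 1:
                rr, cc = rr[:-1], cc[:-1]  # joint pixel belongs to the next segment
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            acc[rr[ok], cc[ok]] += speed
            ang_sin[rr[ok], cc[ok]] += np.sin(theta)
            ang_cos[rr[ok], cc[ok]] += np.cos(theta)
            count[rr[ok], cc[ok]] += 1
    mag = np.divide(acc, count, out=np.zeros_like(acc), where=count > 0)
    theta = np.arctan2(ang_sin, ang_cos)
    angle = np.where(count > 0, scale_angle(theta), 0.0)
    return VelocityMap(magnitude=mag, angle=angle)


def tracks_to_csv(tracks: list[Track], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["track_id", "frame", "row", "col", "v_row", "v_col"])
        for tid, tr in enumerate(tracks):
            vels = tr.velocities
            for i, lo in enumerate(tr.localizations):
                vr, vc = (vels[min(i, len(vels) - 1)] if len(vels) else (0.0, 0.0))
                writer.writerow([tid, lo.frame, f"{lo.row:.3f}", f"{lo.col:.3f}", f"{vr:.4f}", f"{vc:.4f}"])
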