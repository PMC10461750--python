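"""Microbubble advection through a directed vessel graph.

Bubbles are initialized proportionally to segment volume, advected along edge
centerlines with a configurable lateral velocity profile, branch at junctions
with area-weighted probabilities, and are re-injected on their edge of origin
when they exit at a leaf, so the population count is conserved.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import h5py
import numpy as np

from smv.vessel_graph import VesselGraph

__all__ = [
    "Microbubble",
    "SimConfig",
    "FlowState",
    "FlowRecord",
    "initialize_bubbles",
    "local_axial_velocity",
    "branch_probabilities",
    "step",
    "simulate",
    "save_record_hdf5",
    "load_record_hdf5",
    "save_record_csv",
]

#: keeps bubbles strictly inside the wall
WALL_EPS = 1e-3

#: traversal guard: max edges a bubble may cross in one timestep
MAX_TRAVERSALS = 100


@dataclass
class Microbubble:
    """State tuple of one bubble.

    e_orig / e_curr are edge ids; d_ax is the axial arc-length position on the
    current edge (px); d_lat the signed lateral offset from the centerline
    (px); amp the scattering amplitude in (0, 1].
    """

    e_orig: int
    e_curr: int
    d_ax: float
    d_lat: float
    amp: float
    mb_id: int = -1
    psf_index: int = -1  # renderer-assigned PSF patch, fixed for a lifetime


@dataclass
class SimConfig:
    N: int = 50
    dt: float = 1.0  # ms
    T: int = 16
    jitter_sigma: float = 0.1  # px
    profile_exponent: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.profile_exponent not in (1, 2):
            raise ValueError("profile_exponent must be 1 or 2")


@dataclass
class FlowState:
    bubbles: list[Microbubble]
    rng: np.random.Generator
    next_id: int = 0


@dataclass
class FrameRecord:
    """Per-timestep snapshot of the live population."""

    positions: np.ndarray  # (n, 2) float (row, col)
    amplitudes: np.ndarray  # (n,)
    velocities: np.ndarray  # (n, 2) float (v_row, v_col) px/frame
    mb_ids: np.ndarray  # (n,) int


@dataclass
class FlowRecord:
    frames: list[FrameRecord] = field(default_factory=list)
    shape: tuple[int, int] = (0, 0)
    dt: float = 1.0

    def __len__(self) -> int:
        return len(self.frames)


def local_axial_velocity(
    v_ref: float, d_lat: float, r: float, profile_exponent: int = 1
) -> float:
    """Axial speed at lateral offset ``d_lat`` in a tube of radius ``r``.

    v_ax = v_ref * (1 - (|d_lat|/r)**p). p=1 is the linear profile used in
    the flow model; p=2 the physically parabolic option.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    u = min(abs(d_lat) / r, 1.0)
    return v_ref * (1.0 - u**profile_exponent)


def branch_probabilities(outgoing_radii) -> np.ndarray:
    """p_j = pi r_j^2 / sum_i pi r_i^2 over the outgoing edges."""
    radii = np.asarray(outgoing_radii, dtype=float)
    if radii.size == 0:
        raise ValueError("no outgoing radii")
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    areas = np.pi * radii**2
    return areas / areas.sum()


def initialize_bubbles(g: VesselGraph, cfg: SimConfig) -> FlowState:
    """Place N bubbles, n_e ~ (a_e/A)*N per edge via largest-remainder rounding."""
    rng = np.random.default_rng(cfg.rng_seed)
    if cfg.N > 0 and len(g.edges) == 0:
        raise ValueError("cannot place bubbles on an empty graph")
    state = FlowState(bubbles=[], rng=rng)
    if cfg.N == 0 or len(g.edges) == 0:
        return state
    volumes = np.array([e.volume for e in g.edges], dtype=float)
    counts = _largest_remainder(volumes / volumes.sum() * cfg.N, cfg.N)
    for eid, n_e in enumerate(counts):
        e = g.edges[eid]
        length = e.length
        for _ in range(n_e):
            d_ax = float(rng.uniform(0.0, length))
            r = e.radius_at(d_ax)
            d_lat = float(rng.uniform(-(r - WALL_EPS), r - WALL_EPS)) if r > WALL_EPS else 0.0
            amp = _uniform_open_closed(rng)
            state.bubbles.append(
                Microbubble(eid, eid, d_ax, d_lat, amp, mb_id=state.next_id)
            )
            state.next_id += 1
    return state


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(quotas).astype(int)
    short = total - floors.sum()
    if short > 0:
        order = np.argsort(-(quotas - floors), kind="stable")
        floors[order[:short]] += 1
    return floors


def _uniform_open_closed(rng: np.random.Generator) -> float:
    return float(1.0 - rng.uniform(0.0, 1.0))  # U(0, 1]


def step(state: FlowState, g: VesselGraph, cfg: SimConfig) -> FlowState:
    """Advance every bubble by one timestep in place.

    Displacement that overruns the current edge triggers traversal: leaf exits
    re-inject a fresh bubble at the start of the origin edge; junctions pick
    an outgoing edge with area-weighted probability and carry over the
    remaining displacement.
    """
    rng = state.rng
    for i, mb in enumerate(state.bubbles):
        e = g.edges[mb.e_curr]
        r = max(e.radius_at(mb.d_ax), WALL_EPS)
        v_ax = local_axial_velocity(e.v_ref, mb.d_lat, r, cfg.profile_exponent)
        disp = v_ax * cfg.dt
        guard = 0
        while mb.d_ax + disp > e.length:
            guard += 1
            if guard > MAX_TRAVERSALS:
                raise RuntimeError(
                    "bubble traversed too many edges in one step (pathological graph)"
                )
            disp -= e.length - mb.d_ax
            end_vertex = e.v
            outgoing = g.outgoing(end_vertex)
            if not outgoing:
                # leaf exit: the old bubble is removed and a fresh one is
                # injected at the start of its origin edge (no carried-over
                # displacement; it starts moving next step)
                mb = _reinject(mb, g, rng, state.next_id)
                state.bubbles[i] = mb
                state.next_id += 1
                e = g.edges[mb.e_curr]
                disp = 0.0
                break
            else:
                radii = [max(g.edges[eid].radii[0], WALL_EPS) for eid in outgoing]
                probs = branch_probabilities(radii)
                eid = int(rng.choice(len(outgoing), p=probs))
                mb.e_curr = outgoing[eid]
                e = g.edges[mb.e_curr]
                mb.d_ax = 0.0
        mb.d_ax += disp
        r = max(e.radius_at(mb.d_ax), WALL_EPS)
        if cfg.jitter_sigma > 0:
            mb.d_lat += float(rng.normal(0.0, cfg.jitter_sigma))
        mb.d_lat = float(np.clip(mb.d_lat, -(r - WALL_EPS), r - WALL_EPS))
    return state


def _reinject(
    mb: Microbubble, g: VesselGraph, rng: np.random.Generator, new_id: int
) -> Microbubble:
    e = g.edges[mb.e_orig]
    r = max(e.radius_at(0.0), WALL_EPS)
    d_lat = float(rng.uniform(-(r - WALL_EPS), r - WALL_EPS)) if r > WALL_EPS else 0.0
    return Microbubble(
        e_orig=mb.e_orig,
        e_curr=mb.e_orig,
        d_ax=0.0,
        d_lat=d_lat,
        amp=_uniform_open_closed(rng),
        mb_id=new_id,  # fresh identity: forces a new PSF downstream
    )


def simulate(g: VesselGraph, cfg: SimConfig, state: FlowState | None = None) -> FlowRecord:
    """Run T update steps and record positions/amplitudes/velocities."""
    if state is None:
        state = initialize_bubbles(g, cfg)
    record = FlowRecord(frames=[], shape=tuple(g.shape), dt=cfg.dt)
    for _ in range(cfg.T):
        step(state, g, cfg)
        record.frames.append(_snapshot(state, g, cfg))
    return record


def _snapshot(state: FlowState, g: VesselGraph, cfg: SimConfig) -> FrameRecord:
    n = len(state.bubbles)
    pos = np.zeros((n, 2))
    amp = np.zeros(n)
    vel = np.zeros((n, 2))
    ids = np.zeros(n, dtype=int)
    for i, mb in enumerate(state.bubbles):
        e = g.edges[mb.e_curr]
        tangent = e.tangent_at(mb.d_ax)
        normal = np.array([-tangent[1], tangent[0]])
        pos[i] = e.point_at(mb.d_ax) + mb.d_lat * normal
        amp[i] = mb.amp
        r = max(e.radius_at(mb.d_ax), WALL_EPS)
        v_ax = local_axial_velocity(e.v_ref, mb.d_lat, r, cfg.profile_exponent)
        vel[i] = v_ax * tangent
        ids[i] = mb.mb_id
    return FrameRecord(positions=pos, amplitudes=amp, velocities=vel, mb_ids=ids)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_record_hdf5(record: FlowRecord, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["dt"] = record.dt
        fh.attrs["shape"] = record.shape
        for t, fr in enumerate(record.frames):
            grp = fh.create_group(f"frame_{t:05d}")
            grp.create_dataset("positions", data=fr.positions)
            grp.create_dataset("amplitudes", data=fr.amplitudes)
            grp.create_dataset("velocities", data=fr.velocities)
            grp.create_dataset("mb_ids", data=fr.mb_ids)


def load_record_hdf5(path: str) -> FlowRecord:
    with h5py.File(path, "r") as fh:
        record = FlowRecord(frames=[], shape=tuple(fh.attrs["shape"]), dt=float(fh.attrs["dt"]))
        for key in sorted(fh.keys()):
            grp = fh[key]
            record.frames.append(
                FrameRecord(
                    positions=grp["positions"][()],
                    amplitudes=grp["amplitudes"][()],
                    velocities=grp["velocities"][()],
                    mb_ids=grp["mb_ids"][()],
                )
            )
    return record


def save_record_csv(record: FlowRecord, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "mb_id", "row", "col", "amp", "v_row", "v_col"])
        for t, fr in enumerate(record.frames):
            for i in range(len(fr.amplitudes)):
                writer.writerow(
                    [
                        t,
                        int(fr.mb_ids[i]),
                        f"{fr.positions[i, 0]:.4f}",
                        f"{fr.positions[i, 1]:.4f}",
                        f"{fr.amplitudes[i]:.4f}",
                        f"{fr.velocities[i, 0]:.5f}",
                        f"{fr.velocities[i, 1]:.5f}",
                    ]
                )
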