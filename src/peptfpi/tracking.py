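"""Sliding-window detection and two-frame nearest-neighbor trajectory linking.

A scan is sliced into overlapping time frames (default 60 s windows
advanced 3 s — 57 s of overlap), particle images are detected per frame,
and detections are linked frame-to-frame by greedy nearest-neighbor
association with a maximum displacement gate.  Short trajectories, the
signature of background fluctuations, are discarded by a minimum-length
filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cl_io import CLStream, select_window
from .fpi_detect import Detection, FPIParams, detect_from_raw
from .voxel_density import GridSpec, tally_from_flat, voxelize_stream

__all__ = [
    "WindowScheme",
    "LinkParams",
    "Trajectory",
    "TruncatedScanError",
    "make_windows",
    "link_frames",
    "optimal_matching",
    "filter_trajectories",
    "track",
    "write_trajectories",
    "summary_table",
    "gap_report",
]


class TruncatedScanError(ValueError):
    """The scan is shorter than a single analysis window."""


@dataclass(frozen=True)
class WindowScheme:
    """Overlapping frame scheme: window length and step, seconds."""

    length_s: float = 60.0
    step_s: float = 3.0

    def __post_init__(self):
        if not (0 < self.step_s <= self.length_s):
            raise ValueError("require 0 < step_s <= length_s")


@dataclass(frozen=True)
class LinkParams:
    """Association gate and trajectory acceptance threshold.

    ``max_disp_mm`` defaults to 10 mm, the two-particle resolving limit of
    the default detection settings; ``min_length_frames`` of 20 suppresses
    spurious short tracks seeded by background fluctuations.
    """

    max_disp_mm: float = 10.0
    min_length_frames: int = 20

    def __post_init__(self):
        if self.max_disp_mm <= 0:
            raise ValueError("max_disp_mm must be positive")
        if self.min_length_frames < 1:
            raise ValueError("min_length_frames must be >= 1")


@dataclass
class Trajectory:
    """Time-ordered detections attributed to a single particle."""

    id: int
    detections: list[Detection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def times_s(self) -> np.ndarray:
        return np.array([d.frame_time_s for d in self.detections])

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.position for d in self.detections]).reshape(-1, 3)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([d.sigma for d in self.detections]).reshape(-1, 3)


def make_windows(
    scan_start_s: float, scan_end_s: float, scheme: WindowScheme | None = None
) -> list[tuple[float, float, float]]:
    """Frame windows ``(start_s, length_s, frame_time_s)``.

    Windows begin at ``scan_start`` and advance by the step while the full
    window still fits in the scan.  The representative frame time is the
    window center.  A scan shorter than one window raises
    :class:`TruncatedScanError` rather than silently returning nothing.
    """
    scheme = scheme or WindowScheme()
    span = scan_end_s - scan_start_s
    if span < scheme.length_s:
        raise TruncatedScanError(
            f"scan of {span:g} s is shorter than one {scheme.length_s:g} s window"
        )
    n = int(math.floor((span - scheme.length_s) / scheme.step_s + 1e-9)) + 1
    out = []
    for i in range(n):
        start = scan_start_s + i * scheme.step_s
        out.append((start, scheme.length_s, start + scheme.length_s / 2.0))
    return out


def link_frames(
    frames: list[list[Detection]], params: LinkParams | None = None
) -> list[Trajectory]:
    """Greedy two-frame nearest-neighbor linking.

    Between consecutive frames, (trajectory head, new detection) pairs
    within ``max_disp_mm`` are associated in ascending order of distance,
    each head and each detection used at most once.  Unmatched detections
    seed new trajectories; a head unmatched in the next frame terminates —
    there is no coasting, so consecutive detections in a trajectory are one
    frame step apart.  Output is sorted by start time and re-numbered.
    """
    params = params or LinkParams()
    trajs: list[list[Detection]] = []
    active: list[int] = []  # indices into trajs extended in the previous frame
    for dets in frames:
        new_active: list[int] = []
        used_det = [False] * len(dets)
        if active and dets:
            heads = np.array([trajs[t][-1].position for t in active])
            pos = np.array([d.position for d in dets])
            D = cdist(heads, pos)
            pairs = [
                (D[i, j], i, j)
                for i in range(len(active))
                for j in range(len(dets))
                if D[i, j] <= params.max_disp_mm
            ]
            pairs.sort(key=lambda p: (p[0], p[1], p[2]))
            used_head = [False] * len(active)
            for _, i, j in pairs:
                if used_head[i] or used_det[j]:
                    continue
                used_head[i] = True
                used_det[j] = True
                trajs[active[i]].append(dets[j])
                new_active.append(active[i])
        for j, d in enumerate(dets):
            if not used_det[j]:
                trajs.append([d])
                new_active.append(len(trajs) - 1)
        active = new_active
    ordered = sorted(trajs, key=lambda t: t[0].frame_time_s)
    return [Trajectory(i, dets) for i, dets in enumerate(ordered)]


def optimal_matching(
    heads: np.ndarray, dets: np.ndarray, max_disp: float
) -> list[tuple[int, int]]:
    """Exhaustive minimum-total-distance matching (validation oracle).

    Enumerates every injective gated assignment, keeping the one with the
    most pairs and, among those, the smallest total distance.  Exponential;
    intended for small frames (a handful of particles).
    """
    D = cdist(np.atleast_2d(heads), np.atleast_2d(dets))
    nh, nd = D.shape
    best: tuple[int, float, list[tuple[int, int]]] = (0, 0.0, [])

    def rec(i: int, used: set[int], total: float, pairs: list[tuple[int, int]]):
        nonlocal best
        if i == nh:
            key = (len(pairs), -total)
            if key > (best[0], -best[1]):
                best = (len(pairs), total, list(pairs))
            return
        rec(i + 1, used, total, pairs)  # head i unmatched
        for j in range(nd):
            if j not in used and D[i, j] <= max_disp:
                pairs.append((i, j))
                used.add(j)
                rec(i + 1, used, total + D[i, j], pairs)
                used.discard(j)
                pairs.pop()

    rec(0, set(), 0.0, [])
    return best[2]


def filter_trajectories(
    trajs: list[Trajectory], min_length_frames: int
) -> list[Trajectory]:
    """Keep trajectories with at least ``min_length_frames`` detections."""
    return [t for t in trajs if len(t) >= min_length_frames]


def track(
    stream: CLStream,
    spec: GridSpec,
    fpi: FPIParams | None = None,
    scheme: WindowScheme | None = None,
    link: LinkParams | None = None,
    scan_start_s: float | None = None,
    scan_end_s: float | None = None,
) -> list[Trajectory]:
    """Full pipeline: windows -> per-frame detection -> linking -> filtering.

    Scan bounds default to the stream's time extrema rounded outward to
    whole seconds.  Line-voxel traversal is computed once and shared by the
    overlapping windows.  Deterministic for fixed inputs.
    """
    fpi = fpi or FPIParams()
    scheme = scheme or WindowScheme()
    link = link or LinkParams()
    if len(stream) == 0:
        return []
    if scan_start_s is None:
        scan_start_s = math.floor(stream.t_start_ms / 1000.0)
    if scan_end_s is None:
        scan_end_s = math.ceil(stream.t_end_ms / 1000.0)
    windows = make_windows(scan_start_s, scan_end_s, scheme)
    flat_ids, offsets = voxelize_stream(stream, spec)
    frames: list[list[Detection]] = []
    for start, length, ftime in windows:
        lo = int(round(start * 1000))
        hi = int(round((start + length) * 1000))
        i0 = int(np.searchsorted(stream.t_ms, lo, side="left"))
        i1 = int(np.searchsorted(stream.t_ms, hi, side="left"))
        raw = tally_from_flat(flat_ids[offsets[i0] : offsets[i1]], spec)
        frames.append(detect_from_raw(raw, fpi, frame_time_s=ftime))
    trajs = link_frames(frames, link)
    return filter_trajectories(trajs, link.min_length_frames)


def write_trajectories(trajs: list[Trajectory], outdir) -> list[str]:
    """One text file per trajectory: t_ms x y z sx sy sz (mm)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in trajs:
        path = outdir / f"trajectory_{t.id:04d}.txt"
        with open(path, "w") as fh:
            for d in t.detections:
                x, y, z = d.position
                sx, sy, sz = d.sigma
                fh.write(
                    f"{int(round(d.frame_time_s * 1000))} "
                    f"{x:.4f} {y:.4f} {z:.4f} {sx:.4f} {sy:.4f} {sz:.4f}\n"
                )
        paths.append(str(path))
    return paths


def summary_table(trajs: list[Trajectory]) -> pd.DataFrame:
    """Per-trajectory summary: id, time span, length, mean uncertainties."""
    rows = []
    for t in trajs:
        sig = t.sigmas
        rows.append(
            {
                "id": t.id,
                "start_s": t.times_s[0] if len(t) else np.nan,
                "end_s": t.times_s[-1] if len(t) else np.nan,
                "n_frames": len(t),
                "mean_sx_mm": sig[:, 0].mean() if len(t) else np.nan,
                "mean_sy_mm": sig[:, 1].mean() if len(t) else np.nan,
                "mean_sz_mm": sig[:, 2].mean() if len(t) else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "start_s",
            "end_s",
            "n_frames",
            "mean_sx_mm",
            "mean_sy_mm",
            "mean_sz_mm",
        ],
    )


def gap_report(
    trajs: list[Trajectory], max_disp_mm: float = 10.0, max_gap_s: float = 30.0
) -> pd.DataFrame:
    """Candidate occlusions: trajectory ends followed by nearby starts.

    Automatic re-linking across detection gaps is deliberately not
    performed (occlusions are a judgment call); this report lists
    end/start pairs within the spatial gate and time gap to aid manual
    inspection.
    """
    rows = []
    for a in trajs:
        if not len(a):
            continue
        end_t = a.times_s[-1]
        end_p = a.positions[-1]
        for b in trajs:
            if b.id == a.id or not len(b):
                continue
            gap = b.times_s[0] - end_t
            dist = float(np.linalg.norm(b.positions[0] - end_p))
            if 0 < gap <= max_gap_s and dist <= max_disp_mm:
                rows.append(
                    {
                        "end_id": a.id,
                        "start_id": b.id,
                        "gap_s": gap,
                        "distance_mm": dist,
                    }
                )
    return pd.DataFrame(rows, columns=["end_id", "start_id", "gap_s", "distance_mm"])
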