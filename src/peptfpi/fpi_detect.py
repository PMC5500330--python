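"""Feature-point identification on the smoothed line-density grid.

Particle images are local maxima of the smoothed CL-crossing grid: voxels
in the upper r-th percentile of the frame's nonzero values that also beat
every neighbor within a cube of side ``2w+1``.  Each maximum is refined to
sub-voxel precision by an intensity-weighted centroid over the same cube,
and a per-axis statistical uncertainty (standard deviation of the mean) is
attached using the raw CL-crossing count in the cube as the effective
sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cl_io import CLStream
from .voxel_density import GridSpec, LineDensityGrid, smooth_boxcar, tally_lines

__all__ = [
    "FPIParams",
    "Detection",
    "DegenerateDetectionError",
    "find_local_maxima",
    "refine_centroid",
    "estimate_uncertainty",
    "detect_frame",
    "detect_from_raw",
]


class DegenerateDetectionError(RuntimeError):
    """A centroid or uncertainty was requested over an empty cube."""


@dataclass(frozen=True)
class FPIParams:
    """Detection parameters.

    f : box-car smoothing half-width in voxels.
    r : intensity-threshold parameter.  With ``r_mode="percent"`` (default)
        a candidate must lie in the top r percent of the frame's nonzero
        smoothed values (r = 0.3 -> 99.7th percentile); with
        ``r_mode="fraction"`` r is read as a fraction (r = 0.3 -> top 30%).
    w : apparent particle radius in voxels; sets both the local-maximum
        neighborhood and the centroid cube, side ``2w+1``, and hence the
        two-particle resolving limit (~``(2w+1) * voxel_size``).
    """

    f: int = 1
    r: float = 0.3
    w: int = 4
    r_mode: str = "percent"

    def __post_init__(self):
        if self.f < 0:
            raise ValueError("f must be >= 0")
        if not (0 < self.r < 100):
            raise ValueError("r must be in (0, 100)")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if self.r_mode not in ("percent", "fraction"):
            raise ValueError("r_mode must be 'percent' or 'fraction'")


@dataclass
class Detection:
    """A refined particle position for one time frame."""

    frame_time_s: float
    position: np.ndarray  # (3,) mm
    sigma: np.ndarray  # (3,) mm, per-axis standard deviation of the mean
    peak_value: float  # smoothed CL density at the seeding maximum
    n_lines: int  # raw CL crossings summed over the centroid cube
    seed: tuple[int, int, int] = field(default=(0, 0, 0))


def _cube_slices(seed, w, dims):
    return tuple(
        slice(max(seed[a] - w, 0), min(seed[a] + w + 1, dims[a])) for a in range(3)
    )


def find_local_maxima(
    grid: LineDensityGrid, r: float = 0.3, w: int = 4, r_mode: str = "percent"
) -> list[tuple[int, int, int]]:
    """Seed voxels: upper-percentile values that dominate their neighborhood.

    A voxel qualifies if its smoothed value reaches the intensity threshold
    implied by ``r`` (percentile taken over the frame's *nonzero* values,
    so empty space does not drag the threshold to zero) and is strictly
    greater than every other voxel within its clipped ``(2w+1)^3`` cube.
    An equal-valued plateau keeps only its lexicographically smallest
    index.  An all-zero grid yields no maxima.
    """
    vals = grid.counts
    nz = vals[vals > 0]
    if nz.size == 0:
        return []
    q = 100.0 - r if r_mode == "percent" else 100.0 - 100.0 * r
    thr = np.percentile(nz, q)
    maxf = ndimage.maximum_filter(vals, size=2 * w + 1, mode="constant", cval=-np.inf)
    cand = np.argwhere((vals >= thr) & (vals > 0) & (vals == maxf))
    out: list[tuple[int, int, int]] = []
    for ijk in cand:  # argwhere output is already lexicographically sorted
        seed = tuple(int(v) for v in ijk)
        sl = _cube_slices(seed, w, vals.shape)
        cube = vals[sl]
        v = vals[seed]
        eq = np.argwhere(cube == v) + np.array([s.start for s in sl])
        # strict dominance except over plateau partners; smallest index wins
        if np.any(cube > v):
            continue
        if any(tuple(e) < seed for e in map(tuple, eq.tolist())):
            continue
        out.append(seed)
    return out


def refine_centroid(grid: LineDensityGrid, seed, w: int) -> np.ndarray:
    """Intensity-weighted centroid (mm) over the (2w+1)^3 cube about ``seed``.

    Weights are the smoothed CL densities; coordinates are voxel centers.
    The cube is clipped at grid edges and the normalization K sums only
    in-bounds voxels.
    """
    sl = _cube_slices(seed, w, grid.spec.dims)
    cube = grid.counts[sl]
    K = cube.sum()
    if K <= 0:
        raise DegenerateDetectionError("centroid cube has zero total density")
    pos = np.empty(3)
    for a in range(3):
        centers = grid.spec.axis_centers(a)[sl[a]]
        shape = [1, 1, 1]
        shape[a] = -1
        pos[a] = (cube * centers.reshape(shape)).sum() / K
    return pos


def estimate_uncertainty(
    raw: LineDensityGrid,
    smoothed: LineDensityGrid,
    seed,
    w: int,
    centroid: np.ndarray,
) -> np.ndarray:
    """Per-axis standard deviation of the mean of the particle image.

    sigma_a = sqrt( sum N'(v) (v_a - centroid_a)^2 / sum N' ) / sqrt(n)
    over the centroid cube, with n the raw CL-crossing total in the cube
    acting as the number of independent samples.
    """
    sl = _cube_slices(seed, w, smoothed.spec.dims)
    cube = smoothed.counts[sl]
    K = cube.sum()
    n_lines = raw.counts[sl].sum()
    if n_lines <= 0 or K <= 0:
        raise DegenerateDetectionError("no raw CL crossings in centroid cube")
    sigma = np.empty(3)
    for a in range(3):
        centers = smoothed.spec.axis_centers(a)[sl[a]]
        shape = [1, 1, 1]
        shape[a] = -1
        dev2 = (centers.reshape(shape) - centroid[a]) ** 2
        sigma[a] = np.sqrt((cube * dev2).sum() / K) / np.sqrt(n_lines)
    return sigma


def detect_from_raw(
    raw: LineDensityGrid, params: FPIParams, frame_time_s: float = 0.0
) -> list[Detection]:
    """Smooth a raw tally and extract refined detections.

    Returns detections sorted by descending peak smoothed density.
    """
    smoothed = smooth_boxcar(raw, params.f)
    seeds = find_local_maxima(smoothed, params.r, params.w, params.r_mode)
    dets = []
    for seed in seeds:
        pos = refine_centroid(smoothed, seed, params.w)
        sig = estimate_uncertainty(raw, smoothed, seed, params.w, pos)
        sl = _cube_slices(seed, params.w, raw.spec.dims)
        dets.append(
            Detection(
                frame_time_s=frame_time_s,
                position=pos,
                sigma=sig,
                peak_value=float(smoothed.counts[seed]),
                n_lines=int(raw.counts[sl].sum()),
                seed=seed,
            )
        )
    dets.sort(key=lambda d: -d.peak_value)
    return dets


def detect_frame(
    lines: CLStream,
    spec: GridSpec,
    params: FPIParams | None = None,
    frame_time_s: float = 0.0,
) -> list[Detection]:
    """Full single-frame pipeline: tally -> smooth -> maxima -> centroid."""
    params = params or FPIParams()
    if len(lines) == 0:
        return []
    raw = tally_lines(lines, spec)
    return detect_from_raw(raw, params, frame_time_s)
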