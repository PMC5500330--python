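"""Coincidence-line voxel back-projection: tally CL crossings on a 3D grid.

Each coincidence line is traced through a cubic voxel grid and every voxel
whose interior it crosses is incremented by one, independent of chord
length — the grid is a histogram of line *crossings*, the 3D analogue of a
greyscale image on which feature-point detection operates.  The grid may
then be smoothed with a zero-padded box-car (moving-average) kernel of
side ``2f+1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cl_io import CLStream

__all__ = [
    "GridSpec",
    "LineDensityGrid",
    "line_voxels",
    "voxelize_stream",
    "tally_lines",
    "tally_from_flat",
    "smooth_boxcar",
    "save_grid",
    "load_grid",
]

_TIE_EPS = 1e-12  # relative segment-parameter length below which a sliver is dropped


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a cubic voxel grid.

    ``origin`` is the minimum corner in mm; voxel ``(i, j, k)`` spans
    ``origin + (i, j, k)*voxel_size`` to the next lattice point, with its
    center at ``origin + (i+0.5, j+0.5, k+0.5)*voxel_size``.  Indexing is
    0-based.
    """

    origin: tuple[float, float, float]
    dims: tuple[int, int, int]
    voxel_size: float = 2.0

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @classmethod
    def from_cylinder(
        cls, radius_mm: float, axial_half_mm: float, voxel_size: float = 2.0
    ) -> "GridSpec":
        """Grid centered on the scanner origin covering a cylindrical FOV.

        x, y span the transaxial diameter; z spans the axial extent.
        """
        nxy = int(np.ceil(2 * radius_mm / voxel_size))
        nz = int(np.ceil(2 * axial_half_mm / voxel_size))
        origin = (
            -nxy * voxel_size / 2.0,
            -nxy * voxel_size / 2.0,
            -nz * voxel_size / 2.0,
        )
        return cls(origin, (nxy, nxy, nz), voxel_size)

    @property
    def nvox(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def upper(self) -> np.ndarray:
        """Maximum corner in mm."""
        return np.asarray(self.origin) + np.asarray(self.dims) * self.voxel_size

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis."""
        return self.origin[axis] + (np.arange(self.dims[axis]) + 0.5) * self.voxel_size

    def voxel_center(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(idx) + 0.5) * self.voxel_size


@dataclass
class LineDensityGrid:
    """A CL-crossing tally (raw) or its box-car-smoothed counterpart."""

    spec: GridSpec
    counts: np.ndarray  # (nx, ny, nz) float64, >= 0
    smoothed: bool = False
    f: int | None = None  # smoothing half-width used, if smoothed


def line_voxels(p1, p2, spec: GridSpec) -> np.ndarray:
    """Indices ``(k, 3)`` of the voxels whose interior segment p1->p2 crosses.

    The segment is clipped to the grid bounds.  Traversal is parametric:
    the segment parameter values at every grid-plane crossing are collected
    and the voxel containing each inter-crossing midpoint is recorded, which
    visits exactly the voxels a 3D DDA would.  A point lying exactly on a
    voxel boundary is assigned to the larger-index voxel along that axis
    (floor convention), and zero-length slivers from corner touches are
    dropped so only interior intersections of positive length count.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    o = np.asarray(spec.origin)
    h = spec.voxel_size
    dims = np.asarray(spec.dims)
    d = p2 - p1
    hi = o + dims * h

    # Clip the segment parameter range to the grid box (slab method).
    tmin, tmax = 0.0, 1.0
    for a in range(3):
        if d[a] == 0.0:
            if p1[a] < o[a] or p1[a] > hi[a]:
                return np.empty((0, 3), dtype=np.int64)
        else:
            ta = (o[a] - p1[a]) / d[a]
            tb = (hi[a] - p1[a]) / d[a]
            if ta > tb:
                ta, tb = tb, ta
            tmin = max(tmin, ta)
            tmax = min(tmax, tb)
    if tmax - tmin <= _TIE_EPS:
        return np.empty((0, 3), dtype=np.int64)

    ts = [np.array([tmin, tmax])]
    for a in range(3):
        if d[a] != 0.0:
            planes = o[a] + h * np.arange(1, dims[a])
            t = (planes - p1[a]) / d[a]
            ts.append(t[(t > tmin) & (t < tmax)])
    t = np.unique(np.concatenate(ts))
    dt = np.diff(t)
    mids = (t[:-1] + t[1:]) / 2.0
    mids = mids[dt > _TIE_EPS]
    if mids.size == 0:
        return np.empty((0, 3), dtype=np.int64)
    pts = p1[None, :] + mids[:, None] * d[None, :]
    idx = np.floor((pts - o) / h).astype(np.int64)
    np.clip(idx, 0, dims - 1, out=idx)
    return np.unique(idx, axis=0)


def voxelize_stream(stream: CLStream, spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Flat voxel ids traversed by each line, in stream order.

    Returns ``(flat_ids, offsets)`` where line ``i`` occupies
    ``flat_ids[offsets[i]:offsets[i+1]]``.  Precomputing this lets
    overlapping time windows reuse the traversal.
    """
    dims = spec.dims
    per_line: list[np.ndarray] = []
    offsets = np.zeros(len(stream) + 1, dtype=np.int64)
    for i in range(len(stream)):
        vox = line_voxels(stream.p1[i], stream.p2[i], spec)
        if len(vox):
            flat = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), dims)
        else:
            flat = np.empty(0, dtype=np.int64)
        per_line.append(flat)
        offsets[i + 1] = offsets[i] + len(flat)
    if per_line:
        flat_ids = np.concatenate(per_line)
    else:
        flat_ids = np.empty(0, dtype=np.int64)
    return flat_ids, offsets


def tally_from_flat(flat_ids: np.ndarray, spec: GridSpec) -> LineDensityGrid:
    """Raw crossing tally from precomputed flat voxel ids."""
    counts = np.bincount(flat_ids, minlength=spec.nvox).astype(float)
    return LineDensityGrid(spec, counts.reshape(spec.dims), smoothed=False)


def tally_lines(stream: CLStream, spec: GridSpec) -> LineDensityGrid:
    """Tally CL crossings over the grid: +1 per voxel a line passes through."""
    flat_ids, _ = voxelize_stream(stream, spec)
    return tally_from_flat(flat_ids, spec)


def smooth_boxcar(grid: LineDensityGrid, f: int) -> LineDensityGrid:
    """Box-car smoothing: each voxel becomes the mean of its (2f+1)^3 cube.

    Out-of-grid voxels are treated as zero and the divisor stays
    ``(2f+1)**3`` everywhere — a zero-padded moving average with no edge
    renormalization.  ``f=0`` is the identity.
    """
    f = int(f)
    if f < 0:
        raise ValueError("smoothing half-width f must be >= 0")
    if f == 0:
        return replace(grid, counts=grid.counts.copy(), smoothed=True, f=0)
    out = ndimage.uniform_filter(grid.counts, size=2 * f + 1, mode="constant", cval=0.0)
    return replace(grid, counts=out, smoothed=True, f=f)


def save_grid(grid: LineDensityGrid, prefix) -> None:
    """Export a grid as flat text plus a JSON sidecar describing the geometry."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".txt"), grid.counts.reshape(grid.spec.dims[0], -1))
    meta = {
        "origin": list(grid.spec.origin),
        "dims": list(grid.spec.dims),
        "voxel_size": grid.spec.voxel_size,
        "smoothed": grid.smoothed,
        "f": grid.f,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_grid(prefix) -> LineDensityGrid:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    spec = GridSpec(tuple(meta["origin"]), tuple(meta["dims"]), meta["voxel_size"])
    counts = np.loadtxt(prefix.with_suffix(".txt")).reshape(spec.dims)
    return LineDensityGrid(spec, counts, smoothed=meta["smoothed"], f=meta["f"])
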