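"""Feature-point detection: maxima selection, centroid refinement, uncertainty."""

import numpy as np
import pytest

from peptfpi import (
    CLStream,
    DegenerateDetectionError,
    FPIParams,
    GridSpec,
    LineDensityGrid,
    PointSource,
    ScannerModel,
    detect_frame,
    estimate_uncertainty,
    find_local_maxima,
    refine_centroid,
    sample_emissions,
    simulate_experiment,
)


def grid_of(arr, voxel=1.0, origin=None):
    arr = np.asarray(arr, float)
    origin = origin or (0.0, 0.0, 0.0)
    return LineDensityGrid(GridSpec(origin, arr.shape, voxel), arr, smoothed=True, f=1)


def maxima_oracle(grid, r, w):
    """Exhaustive scan implementing the threshold + strict-dominance +
    lexicographic-plateau rule directly."""
    vals = grid.counts
    nz = vals[vals > 0]
    if nz.size == 0:
        return []
    thr = np.percentile(nz, 100 - r)
    dims = vals.shape
    out = []
    for seed in np.ndindex(dims):
        v = vals[seed]
        if v <= 0 or v < thr:
            continue
        ok = True
        for other in np.ndindex(
            *(min(seed[a] + w + 1, dims[a]) - max(seed[a] - w, 0) for a in range(3))
        ):
            idx = tuple(other[a] + max(seed[a] - w, 0) for a in range(3))
            if idx == seed:
                continue
            if vals[idx] > v or (vals[idx] == v and idx < seed):
                ok = False
                break
        if ok:
            out.append(seed)
    return out


class TestLocalMaxima:
    def test_single_blob_single_maximum(self):
        a = np.zeros((11, 11, 11))
        a[5, 5, 5] = 10
        a[4:7, 4:7, 4:7] += 1
        assert find_local_maxima(grid_of(a), r=30, w=2) == [(5, 5, 5)]

    def test_two_separated_blobs_two_maxima(self):
        a = np.zeros((20, 7, 7))
        a[3, 3, 3] = 5.0
        a[16, 3, 3] = 5.0  # separation 13 > 2w+1 = 5
        assert find_local_maxima(grid_of(a), r=50, w=2) == [(3, 3, 3), (16, 3, 3)]

    def test_equal_peaks_within_w_keep_lexicographic_smallest(self):
        a = np.zeros((11, 5, 5))
        a[4, 2, 2] = 5.0
        a[6, 2, 2] = 5.0  # within w=4 of each other
        got = find_local_maxima(grid_of(a), r=50, w=4)
        assert got == [(4, 2, 2)]
        assert got == maxima_oracle(grid_of(a), r=50, w=4)

    def test_matches_exhaustive_oracle_on_random_grid(self, rng):
        a = np.round(rng.uniform(0, 9, size=(9, 9, 9)))
        g = grid_of(a)
        assert find_local_maxima(g, r=20, w=2) == maxima_oracle(g, r=20, w=2)

    def test_all_zero_grid_empty(self):
        assert find_local_maxima(grid_of(np.zeros((5, 5, 5)))) == []


class TestCentroid:
    def test_single_nonzero_voxel_returns_its_center(self):
        a = np.zeros((5, 5, 5))
        a[2, 3, 1] = 4.0
        pos = refine_centroid(grid_of(a, voxel=2.0), (2, 3, 1), w=1)
        np.testing.assert_allclose(pos, [5.0, 7.0, 3.0])

    def test_symmetric_pattern_returns_seed_center(self):
        a = np.zeros((7, 7, 7))
        a[3, 3, 3] = 9.0
        for d in (-1, 1):
            a[3 + d, 3, 3] = a[3, 3 + d, 3] = a[3, 3, 3 + d] = 2.0
        pos = refine_centroid(grid_of(a), (3, 3, 3), w=2)
        np.testing.assert_allclose(pos, [3.5, 3.5, 3.5])

    def test_asymmetric_weights_literal_formula(self):
        # weights 1,2,3 at x-centers 1,3,5 mm -> x' = (1*1 + 2*3 + 3*5)/6
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        pos = refine_centroid(grid_of(a, voxel=2.0), (1, 0, 0), w=1)
        assert pos[0] == pytest.approx(22 / 6)
        assert pos[1] == pos[2] == pytest.approx(1.0)

    def test_zero_cube_raises(self):
        a = np.zeros((5, 5, 5))
        a[4, 4, 4] = 1.0
        with pytest.raises(DegenerateDetectionError):
            refine_centroid(grid_of(a), (0, 0, 0), w=1)

    def test_centroid_stays_within_cube(self, rng):
        a = rng.uniform(0, 5, size=(9, 9, 9))
        seed, w = (4, 4, 4), 3
        pos = refine_centroid(grid_of(a), seed, w)
        center = grid_of(a).spec.voxel_center(seed)
        assert np.linalg.norm(pos - center) <= w * 1.0 * np.sqrt(3) + 1e-9


class TestUncertainty:
    def test_single_voxel_zero_spread(self):
        a = np.zeros((5, 5, 5))
        a[2, 2, 2] = 3.0
        raw = LineDensityGrid(grid_of(a).spec, a.copy())
        sig = estimate_uncertainty(raw, grid_of(a), (2, 2, 2), 1, np.array([2.5, 2.5, 2.5]))
        np.testing.assert_allclose(sig, 0.0)

    def test_two_voxel_hand_computation(self):
        # equal weights at x-centers -1 and +1 mm, 4 raw crossings in cube:
        # weighted std = 1 mm, sigma_x = 1/sqrt(4) = 0.5 mm
        spec = GridSpec((-2, -1, -1), (2, 1, 1), 2.0)
        sm = LineDensityGrid(spec, np.array([3.0, 3.0]).reshape(2, 1, 1), smoothed=True, f=1)
        raw = LineDensityGrid(spec, np.array([2.0, 2.0]).reshape(2, 1, 1))
        sig = estimate_uncertainty(raw, sm, (0, 0, 0), 1, np.array([0.0, 0.0, 0.0]))
        assert sig[0] == pytest.approx(0.5)
        np.testing.assert_allclose(sig[1:], 0.0)

    def test_no_raw_crossings_raises(self):
        spec = GridSpec((0, 0, 0), (3, 3, 3), 1.0)
        sm = LineDensityGrid(spec, np.ones((3, 3, 3)), smoothed=True, f=1)
        raw = LineDensityGrid(spec, np.zeros((3, 3, 3)))
        with pytest.raises(DegenerateDetectionError):
            estimate_uncertainty(raw, sm, (1, 1, 1), 1, np.ones(3))


class TestDetectFrame:
    def test_empty_stream_no_detections(self, fov_grid):
        empty = CLStream.from_arrays([], np.empty((0, 3)), np.empty((0, 3)))
        assert detect_frame(empty, fov_grid) == []

    def test_single_bright_source_within_one_voxel(self, rng, scanner, fov_grid):
        src = PointSource.static((12, -8, 20), 1000.0)
        t, p1, p2 = sample_emissions(src, scanner, 0, 10, rng)
        stream = CLStream.from_arrays(t, p1, p2)
        dets = detect_frame(stream, fov_grid, FPIParams())
        assert len(dets) == 1
        assert np.all(np.abs(dets[0].position - [12, -8, 20]) <= 2.0)
        assert np.all(dets[0].sigma >= 0) and dets[0].peak_value > 0

    def test_three_separated_sources_each_found(self, rng, scanner, fov_grid):
        truth = np.array([[-40, 0, -30], [0, 35, 10], [40, -25, 30]], float)
        sources = [PointSource.static(p, 500.0) for p in truth]
        res = simulate_experiment(sources, scanner, 10.0, rng)
        dets = detect_frame(res.stream, fov_grid, FPIParams())
        assert len(dets) == 3
        found = np.array([d.position for d in dets])
        for p in truth:
            assert np.min(np.linalg.norm(found - p, axis=1)) <= 2.0

    def test_translation_equivariance(self, rng):
        # shifting all endpoints by one voxel pitch shifts detections by the
        # same amount, for an interior source on a grid enclosing all lines
        scanner = ScannerModel(ring_radius_mm=30, axial_half_length_mm=30,
                               background_rate_per_s=0.0)
        spec = GridSpec((-50, -50, -50), (50, 50, 50), 2.0)
        src = PointSource.static((3, -5, 2), 2000.0)
        t, p1, p2 = sample_emissions(src, scanner, 0, 5, rng)
        stream = CLStream.from_arrays(t, p1, p2)
        base = detect_frame(stream, spec, FPIParams())
        shifted = CLStream.from_arrays(t, p1 + 2.0, p2 + 2.0)
        moved = detect_frame(shifted, spec, FPIParams())
        assert len(base) == len(moved) == 1
        np.testing.assert_allclose(moved[0].position, base[0].position + 2.0, atol=0.05)

    def test_localization_error_decreases_with_counts(self, scanner, fov_grid):
        # static source, three count levels, error averaged over replicates
        errors = []
        for level, act in enumerate([30.0, 300.0, 3000.0]):
            errs = []
            for rep in range(4):
                rng = np.random.default_rng(1000 + 10 * level + rep)
                src = PointSource.static((15, 10, -5), act)
                t, p1, p2 = sample_emissions(src, scanner, 0, 10, rng)
                stream = CLStream.from_arrays(t, p1, p2)
                dets = detect_frame(stream, fov_grid, FPIParams())
                d = min(dets, key=lambda d: np.linalg.norm(d.position - [15, 10, -5]))
                errs.append(np.linalg.norm(d.position - [15, 10, -5]))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]
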