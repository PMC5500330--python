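# Methods

## Problem and model

A point-like positron source produces back-to-back 511 keV gammas; the
detector pair that fires in coincidence defines a coincidence line (CL)
passing near the source. Over a time frame, the CLs from a point source
form a bundle whose crossing density peaks at the source, while random
coincidences (e.g. intrinsic ¹⁷⁶Lu decays in LSO crystals) form a broad,
cluster-free background. The FPI approach treats the 3D histogram of CL
crossings per voxel as a volumetric greyscale image and applies optical
feature-point techniques (box-car smoothing, percentile-thresholded local
maxima, centroid refinement) to locate an *a priori* unknown number of
sources per frame, then links frames into trajectories.

## Pipeline and parameters

1. **Windowing** (`tracking.WindowScheme`): frames of `length_s` = 60 s
   advanced by `step_s` = 3 s (57 s overlap). The defaults follow Poisson
   planning for a 32 Bq cell at 5.2% sensitivity (rate λ = 1.664 /s): 3 s
   is the smallest integer step with P(0 events) = e^(−3λ) < 1%, and 60 s
   collects ~100 events per cell, enough for stable triangulation. The
   representative frame time is the window **center**; the window overlap
   intentionally low-passes the trajectories. A scan shorter than one
   window raises an explicit error.
2. **Tally** (`voxel_density`): each CL increments by exactly 1 every
   voxel whose interior it crosses (crossings, not chord lengths). The
   traversal is the parametric plane-crossing form of amortized 3D ray
   marching: all grid-plane crossing parameters along the clipped segment
   are sorted and each inter-crossing midpoint indexes one voxel. Points
   exactly on a voxel boundary go to the larger index (floor convention);
   zero-length corner touches are dropped. Default grid: 2 mm cubic
   voxels centered on the scanner origin, spanning the full transaxial
   and axial FOV.
3. **Smoothing**: zero-padded box-car mean over a (2f+1)³ cube with the
   divisor fixed at (2f+1)³ everywhere (no edge renormalization), f = 1.
   Implemented with `scipy.ndimage.uniform_filter(mode="constant")`.
4. **Detection** (`fpi_detect`): candidate voxels must (a) reach the
   (100 − r)-th percentile of the frame's **nonzero** smoothed values
   (r = 0.3 ⇒ top 0.3%; restricting to nonzero voxels keeps the empty FOV
   from collapsing the threshold) and (b) strictly exceed every other
   voxel within a (2w+1)³ cube, w = 4; an equal-valued plateau keeps only
   its lexicographically smallest index, making detection deterministic.
   The percent reading of r follows the optical feature-point convention;
   `r_mode="fraction"` selects the top-30% alternative. Positions are
   refined by the N′-weighted centroid of voxel centers over the same
   clipped cube.
5. **Uncertainty**: per axis, the weighted standard deviation of the
   particle image about the centroid divided by √n, with n the raw
   CL-crossing total in the centroid cube — a purely statistical
   "standard deviation of the mean" that ignores motion blur and biases.
6. **Linking** (`tracking`): greedy two-frame nearest neighbors —
   candidate (trajectory head, detection) pairs within `max_disp_mm`
   = 10 mm (the ≈1 cm resolving limit of w = 4 at 2 mm voxels) are
   associated in ascending distance, each used at most once; unmatched
   detections seed new tracks, unmatched heads terminate (no coasting).
   An exhaustive minimum-total-distance matcher is provided as a
   validation oracle for small frames. Trajectories shorter than
   `min_length_frames` = 20 are rejected; background fluctuations do not
   persist coherently for 20 overlapping frames, so this filter removes
   false tracks. Occlusion re-linking is deliberately manual:
   `gap_report` lists end/start pairs within a spatial gate and time gap
   for inspection.

## Synthetic data generator

`simulate` emulates the study conditions of a low-activity cell-tracking
scan inside an Inveon-like cylinder (ring radius 80.5 mm, axial half
length 63.5 mm — configuration, not claims):

- **Sources**: static or piecewise-linear paths; activity decays with the
  ¹⁸F half-life (109.8 min). Event times are an inhomogeneous Poisson
  process with rate activity(t) × sensitivity, sampled by exact thinning
  from the rate at the interval start (decay is monotone).
- **Geometry**: back-to-back collinear gammas with direction uniform on
  the sphere, intersected with the detector cylinder; directions whose
  endpoints miss the axial extent are resampled, folding geometric losses
  into the calibrated scalar sensitivity (default 0.052) so a centered
  source's realized rate is activity × sensitivity by construction.
  Endpoints are jittered by an isotropic Gaussian (σ = 1.5 mm, the
  crystal-pitch scale), standing in for detector resolution; positron
  range and acollinearity are sub-voxel at 2 mm and omitted.
- **Background**: homogeneous Poisson at 170 counts/min with both
  endpoints independent and uniform on the cylinder surface.
- **Determinism**: one `numpy` Generator drives everything; a fixed
  configuration and seed reproduce the CL file byte for byte.

The default 16-cell phantom places 32 Bq sources on a 4×4 transaxial
lattice (30 mm pitch, staggered axial offsets), all separations well
above the 1 cm resolving limit — matching the diluted, well-separated
cell preparation the processing defaults assume.

What the generator does **not** emulate: photon transport and scatter,
energy spectra, attenuation in the sample, detector dead time, block
structure of the crystals, and the slight axial falloff of sensitivity
away from the FOV center. Passing tests on synthetic data therefore
demonstrate the correctness and statistical behavior of the processing
chain under the stated emission model, not scanner-specific image
quality. One visible consequence: with uniform endpoints, background
chord density is center-weighted axially but mildly rim-weighted
transaxially, whereas a real randoms profile peaks at the center of the
image volume in all directions.

## Numerical choices and degenerate inputs

- Timestamps are integer milliseconds; windows are half-open
  [start, start+length) so boundary events are never double-counted.
- Traversal tie-breaks: boundary points to the larger voxel index;
  slivers below 10⁻¹² of the segment parameter dropped.
- Neighborhoods and centroid cubes are clipped at grid edges, never
  wrapped; the centroid normalization K sums in-bounds voxels only.
- A zero cube mass or zero raw-crossing count raises
  `DegenerateDetectionError` (cannot occur for a seed that passed the
  threshold on its own frame).
- Linking ties (equal distances) are broken by head index then detection
  index, keeping output order-deterministic.
- An empty stream yields an empty grid, no detections, no trajectories;
  an all-zero frame yields no maxima.

## Acceptance-scale choices

The end-to-end accuracy measurement simulates five independently seeded
300 s scans of the 16-cell phantom (~8,600 events each) and runs the full
default pipeline (81 frames per scan), about 4 s per scan on one CPU.
Per-axis RMS error of every trajectory point against the matched truth
position averages ≈0.63 mm across seeds — sub-voxel, and below the ≈1 mm
accuracy expected of PEPT at these count rates.

## Known limitations

- The uncertainty divisor (raw crossings in the centroid cube) counts
  every voxel visit of every line, so a 60 s frame yields n ≈ 8×10³ and
  σ ≈ 0.1 mm, noticeably smaller than the realized ~0.6 mm RMS error;
  treating each *distinct* CL as one independent sample would give
  estimates closer to the realized error. The reported σ should be read
  as a relative, not absolute, confidence measure.
- No gap closing: a single missed frame splits a physical track in two
  (by design; see `gap_report`).
- Two sources within the resolving limit merge into one biased detection;
  near-equal activities can also swap identities near the limit.
- The simulator's scalar sensitivity has no axial falloff by default, so
  off-center sources are detected at the center-of-FOV rate.
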