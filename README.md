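# peptfpi

Feature-point-identification (FPI) Positron Emission Particle Tracking:
locating and following **multiple low-activity point-like positron
sources** — down to single radiolabeled cells of a few tens of Bq — from
list-mode PET coincidence data, without reconstructing images.

## Who this is for

PEPT treats every recorded coincidence as a *coincidence line* (CL)
joining the two detector crystals that fired; a point source must lie near
every CL it produced. Where conventional PET reconstruction needs millions
of events, PEPT can locate a point source from a few dozen lines, which
makes it viable for tracking individual ¹⁸F-labeled cells (e.g.
FEX-deleted *S. cerevisiae*, which take up fluoride and cannot export it)
inside a small-animal scanner. The package provides:

- list-mode CL file I/O and time windowing (`peptfpi.cl_io`),
- CL-crossing voxel back-projection and box-car smoothing
  (`peptfpi.voxel_density`),
- feature-point detection with centroid refinement and per-axis
  uncertainties (`peptfpi.fpi_detect`),
- overlapping-window, two-frame nearest-neighbor trajectory linking
  (`peptfpi.tracking`),
- a synthetic list-mode simulator with ground truth (`peptfpi.simulate`),
- Poisson experiment-planning and activity bookkeeping (`peptfpi.rates`),
- a `peptfpi` command-line tool wrapping all of the above.

## The method

For each time frame the number of CL crossings is tallied over a cubic
voxel grid (default 2 mm), giving a line-density "image" N(x, y, z). It is
smoothed with a zero-padded box-car kernel,

    N'(x,y,z) = (2f+1)^-3 · Σ_{|i-x|≤f} Σ_{|j-y|≤f} Σ_{|k-z|≤f} N(i,j,k),

with f = 1 by default. Particle images are voxels whose smoothed value
lies in the upper r-th percentile of the frame's nonzero values (r = 0.3)
*and* exceeds every neighbor within a cube of side 2w+1 (w = 4, which also
sets the ≈1 cm two-particle resolving limit at 2 mm voxels). Each maximum
is refined to sub-voxel precision by the intensity-weighted centroid

    x' = K^-1 · Σ_cube x · N'(x,y,z),   K = Σ_cube N'(x,y,z),

over the same cube, with a per-axis uncertainty taken as the standard
deviation of the mean of the particle image. Frames are 60 s windows
advanced 3 s (57 s overlap) — for a 32 Bq cell seen at 5.2% sensitivity
the expected rate is 1.7 events/s, so 3 s steps make the zero-event
probability < 1% and 60 s windows collect ~100 events per cell. Detections
are linked frame-to-frame by greedy nearest-neighbor association gated at
10 mm, and trajectories shorter than 20 frames are discarded, which
suppresses false tracks from the spatially broad random-coincidence
background (~170 counts/min).

## Worked example

Simulate 16 static 32 Bq cells (5.2% sensitivity, 170 cpm background,
300 s) and track them with the default settings:

```sh
$ peptfpi simulate --n-cells 16 --activity 32 --duration 300 --seed 1 \
      --out-cl phantom_cl.txt --out-truth phantom_truth.txt
wrote 8581 events to phantom_cl.txt

$ peptfpi track phantom_cl.txt --outdir trajs
16 trajectories written to trajs

$ head -3 trajs/summary.csv
id,start_s,end_s,n_frames,mean_sx_mm,mean_sy_mm,mean_sz_mm
0,30.0,270.0,81,0.1047...,0.0988...,0.0826...
1,30.0,270.0,81,0.0974...,0.0984...,0.0798...
```

All 16 sources are recovered as full-length trajectories (81 frames: one
per 3 s step of a 300 s scan). Each `trajectory_NNNN.txt` holds rows
`t_ms x y z sx sy sz` (mm). Comparing tracked positions with the truth
file gives a mean per-axis RMS localization error of about 0.63 mm —
sub-voxel, and consistent with near-millimetre PEPT accuracy at these
count rates.

The planning arithmetic behind those settings is available directly:

```sh
$ peptfpi report
expected CL rate:         1.664 events/s/cell (100 per min)
chosen time step:         3 s (P(0 events) = 0.68 % < 1 %)
window length:            60 s -> 100 events expected per cell per window
```

`peptfpi background` summarizes a background-only scan (count rate and
per-frame peak smoothed line density).

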