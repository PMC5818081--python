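# spheroquant

Quantification toolkit for three workhorse assays of breast-cancer
metastasis research, aimed at imaging and in-vivo labs that currently score
these readouts with one-off ImageJ/MATLAB scripts:

* **Spheroid invasion** — a tumour spheroid embedded in collagen sheds
  single invading cells; from a DAPI z-stack the pipeline max-projects,
  thresholds, splits contacting nuclei by marker-based watershed, and scores
  global invasion as the mean square displacement over the *N* invading
  cells,

  &nbsp;&nbsp;&nbsp;&nbsp;MSD = (1/N) Σₖ dₖ²  [µm²],

  where dₖ is the Euclidean distance from cell *k*'s nucleus centroid to the
  spheroid centroid. (This is a per-snapshot score over cells, not the
  time-lagged MSD of diffusion analysis.)

* **Fibroblast chemotaxis** — time-lapse tracks from a two-reservoir
  chemotaxis slide yield per-cell velocity (µm/min), Euclidean vs
  accumulated distance, the percentage of cells displacing net toward each
  reservoir, and the Rayleigh test of circular uniformity on per-cell
  net-displacement angles.

* **Burden metrics** — calliper tumour volume 0.5236·((width+length)/2)³,
  percentage lung tumour burden (100 × tumour area / lung area) with nodule
  counting above a 1000 µm² minimum area, percentage gel contraction, cell
  roundness (isoperimetric quotient 4πA/P²), and a two-sided single-outlier
  Grubbs screen.

Every stage has a matching **synthetic-data generator** with exact ground
truth (planted nucleus positions and distances, known drift, known nodule
areas, known contraction fraction), so the whole pipeline can be validated
end-to-end without any microscope.

## Worked example

Simulate an invasion assay (40 nuclei around a 100 µm spheroid, 1 µm/px,
3-plane stack) and quantify it:

```sh
$ spheroquant simulate invasion --seed 7 --out demo --n-cells 40
wrote demo/stack.tif
$ spheroquant invasion --stack demo/stack.tif --pixel-size 1.0
{
  "msd_um2": 45207.373360314916,
  "n_cells": 40
}
```

All 40 planted nuclei are recovered and the MSD of 45 207 µm² sits within
0.01% of the generator's ground truth (45 211.6 µm², in
`demo/ground_truth.json`): cells ~130–280 µm from the spheroid centre give a
mean squared distance of this order.

Chemotaxis with a rightward drift of 0.4 µm per 20-min step over 8 h:

```sh
$ spheroquant simulate tracks --seed 7 --out demo_trk --drift 0.4 0.0
$ spheroquant tracks --csv demo_trk/tracks.csv
{
  "n_tracks": 60,
  "pct_toward_left": 11.666666666666666,
  "pct_toward_right": 88.33333333333333,
  "pct_zero": 0.0,
  "rayleigh_R": 0.6641477122806675,
  "rayleigh_p": 4.139234408971005e-12,
  "rayleigh_z": 26.465531023658656
}
```

88% of the 60 cells end up right of where they started and the Rayleigh test
rejects uniform directions decisively (p ≈ 4×10⁻¹²) — the signature of a
real chemotactic gradient, as opposed to the ~50/50 split and p ≈ 1 the same
command prints for zero drift.

The same operations are available as a library
(`spheroquant.segment_invasion`, `compute_msd`, `summarize_track`,
`rayleigh_test`, `quantify_burden`, `grubbs_outliers`, …) returning typed
dataclasses and pandas tables.

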