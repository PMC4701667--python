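# wormbench

A self-contained workbench for maskless-photopatterning experiments with
*C. elegans* on agar plates:

- **patterns** — compile parametric assay geometries (frames, micropillar
  arrays, T-mazes, spirals, rippled channels) and freehand tablet strokes
  into binary DMD mask bitmaps, with world↔DMD coordinate transforms,
  multi-exposure stitching and a Gaussian optical-blur dose model.
- **exposure** — the empirical resolution/exposure calibration table and
  fabrication design rules (50 μm minimum raised feature, resolution-limited
  channels, gap-limited heights, 5-minute diffusion-adhesion rule).
- **wormsim** — a ground-truthed synthetic worm-video simulator: undulatory
  kinematic locomotion, confinement–speed coupling, hinge-pin lever
  mechanics, maze navigation with optional food bias, grayscale rendering.
- **tracker** — the video tracking pipeline: frame differencing, blob
  detection, moment-based centroids and principal-axis orientation, body
  segmentation, and Savitzky-Golay kinematics in μm/s.
- **assays** — per-configuration speed summaries, maze endpoint
  classification (80 %-of-body rule with escape exclusion), exact binomial
  choice tests with Clopper-Pearson intervals, and Kaplan-Meier survival
  with censoring plus a two-group log-rank test.
- **looper** — a closed-loop observe → decide → pattern driver that couples
  tracker output to trigger-based exposures in the simulated environment.
- **io / cli** — frame-stack and CSV I/O with versioned schemas, and the
  `wormbench` command-line entry point.

## CLI

```bash
wormbench design --pattern t_maze --channel-width 200 --objective 5 --out mask.png
wormbench draw --stream strokes.csv --out drawn.png
wormbench calibrate
wormbench simulate --scenario open_frame --seed 1 --duration 30 --out vid/
wormbench track --input vid/ --out traj.csv
wormbench analyze speed --in traj.csv --windows open:0:200 --out speed.csv
wormbench analyze choice --left 19 --right 19
wormbench analyze survival --in survival.csv --out km.json
wormbench run-loop --seed 1 --duration 12 --out log.jsonl
```

## Conventions

- World coordinates: μm, y-up, origin at the projected field centre.
- Images/DMD: 0-based `(row, col)`, y-down, pixel centres on integer
  indices; masks are strictly binary (pixel set ⇔ centre inside the exposed
  solid region).
- All trajectory outputs are in μm and seconds, never raw pixels.
- Every simulation and pipeline run is deterministic given its seed.
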