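# smv — localization-free super-resolution microbubble velocimetry

`smv` reconstructs super-resolved blood-flow velocity maps directly from
contrast-ultrasound frame sequences, without localizing or tracking individual
microbubbles. It contains the full training/evaluation pipeline:

- **vessel_graph** — vascular template images → directed, velocity-annotated
  vessel graphs (adaptive-threshold segmentation, medial-axis skeletonization,
  skeleton→graph conversion, BFS orientation from the widest endpoint,
  radius→velocity assignment), plus a synthetic branching-template generator.
- **flow_sim** — microbubble advection on the graph: volume-proportional
  seeding, lateral flow profile, area-weighted branching at junctions,
  re-injection at leaves (population is conserved).
- **image_synth** — PSF-convolution rendering of flow records into magnitude
  frames (per-bubble persistent PSF patch, sub-pixel bilinear splatting,
  Rayleigh electronic noise) and rasterization of dense 2-channel
  (magnitude px/ms, angle scaled to [0,1]) ground-truth maps; dataset builder.
- **velocity_net** — a convolutional LSTM-UNet implemented directly on numpy
  (im2col-free shifted-matmul convolutions, analytic backprop, Adam). Per-frame
  encoder features feed a ConvLSTM bottleneck; the final hidden state is
  decoded with UNet skips into a 2×H×W velocity map. MSE loss.
- **inference** — block-wise application (LSTM state reset per 16-frame
  block), conversion to physical units (mm/s, radians), temporal accumulation,
  ROI pulsatility traces, even/odd split reconstructions.
- **baseline_ulm** — conventional localize–pair–track velocimetry (NCC +
  sub-pixel centroid, greedy/Kalman nearest-neighbour linking, track
  splatting) used as an independent oracle and comparison arm.
- **evaluation** — vessel-masked velocity RMSE (px/frame and mm/s), FWHM with
  interpolated half-maximum crossings, Fourier ring correlation resolution
  (half-bit and 2-sigma criteria), mass-conservation channel references, bias
  tables.

## CLI

```sh
smv template --width 128 --height 128 --seed 1 --out template.tiff
smv graph --template template.tiff --out graph.json
smv simulate --graph graph.json --n-bubbles 50 --n-steps 16 --out record.h5
smv render --record record.h5 --out frames.tiff
smv make-dataset --n-samples 20 --patch 64 --out dataset.h5
smv train --dataset dataset.h5 --depth 2 --base-width 8 --epochs 30 --out model
smv infer --model model --input frames.tiff --block 16 --pixel-um 4.9 \
          --frame-ms 1.0 --out velocity.tiff
smv baseline --frames frames.tiff --out tracks.csv
smv evaluate --pred velocity.tiff --truth truth.tiff --out metrics.json
smv pipeline --config config.yaml     # staged end-to-end run from YAML
```

`smv pipeline` validates the YAML config (unknown keys are reported), logs
every stage's named seed, and is reproducible: identical config + seeds give
identical artifacts.

## Conventions

- Grids are (row, col); angles are atan2(Δrow, Δcol) scaled from [−π, π] to
  [0, 1] for training targets.
- Velocities are pixels/frame internally; `to_physical` converts with
  v[mm/s] = px/frame × pixel_size[μm] / frame_interval[ms]
  (defaults 4.9 μm, 1 ms).
- All randomness flows through named integer seeds; fixed seeds reproduce
  datasets, simulations and training histories.
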