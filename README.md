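# callusmech

Time-lapsed analysis of bone-defect healing from 3D mineral-density image
series: multi-density segmentation, automatic volume-of-interest definition,
voxel micro-finite-element strain estimation, and mechanoregulation
statistics (ROC association of strain with mineralisation, and two-threshold
mechanostat classification of surface remodelling events).

Because no real scan series ships with the package, a synthetic phantom
module generates time-lapsed healing series from a known generative rule
(strain-threshold mineralisation, surface resorption, density maturation,
flip noise) with event-level ground truth, so every downstream stage is
verifiable end to end.

## Modules

| module      | role |
|-------------|------|
| `phantom`   | two-fragment defect phantom, healing simulation, ground-truth event log, image noise |
| `imageproc` | Gaussian smoothing (σ=1.2, support 1), 395–720/25 threshold ladder, translation registration, formation/quiescence/resorption overlays |
| `voi`       | DC/DP/FC/FP partition of the post-operative image (645 binarisation, component labelling, marrow fill, periosteum interpolation, ray casting) |
| `microfe`   | voxel hexahedral FE solver (matrix-free Jacobi-PCG, numba-accelerated), density→modulus law (soft 3 MPa, 4–14 GPa over the ladder), 1%-compression stiffness probe, effective strain `sqrt(2U/E)` |
| `loading`   | load estimation against a homogeneous SED target; two-spring fixator/callus model mapping organ-scale load to image-edge displacements |
| `mechreg`   | ROC/AUC of preceding strain vs mineralisation; surface-state extraction; (T_R, T_F) classifier, normalised confusion matrix, CCR heat maps |
| `kinetics`  | BV/TV time courses and formation/resorption rates per VOI and threshold |
| `pipeline`  | YAML-configured study runner, manifest, report generation |

## CLI

```bash
callusmech phantom --gap-mm 0.85 --steps 5 --seed 1 --out phantom_out
callusmech segment phantom_out/frame_000.mha --ladder "395:720:25"
callusmech voi phantom_out/frame_000.mha --out voi.mha
callusmech solve phantom_out/frame_000.mha bc.json --out strain.h5
callusmech estimate-load shaft.mha --u-target 0.02
callusmech mechreg frame_000.mha frame_001.mha strain.h5 --tau 395
callusmech kinetics voi.mha phantom_out/frame_*.mha
callusmech run study.yaml && callusmech report results/
```

`bc.json` example: `{"kind": "axial_compression", "total_displacement": 0.35}`.

A minimal `study.yaml`:

```yaml
seed: 1
n_frames: 6
material: {soft_modulus: 3.0, nu: 0.3, mode: banded}
loading: {mode: displacement, axial_displacement: 0.35, fe_coarsen: 4, fe_tolerance: 1.0e-6}
phantom:
  geometry: {grid_shape: [96, 96, 160], gap_length: 0.85}
  rule: {strain_threshold_form: 0.30, flip_noise: 0.02, conduction_radius: .inf}
smoothing: {enabled: true, sigma: 1.2, support: 1}
noise_sigma: 0.0
voi: {threshold: 645.0, connectivity: 26}
mechreg: {roc_vois: [DC, DP], heatmap_thresholds: [395.0], heatmap_grid: 64}
```

## Conventions

- Images are `(nx, ny, nz)` arrays of mg HA/cm³; the fragment axis is z;
  voxel size is in µm (default 10.5).
- Units in the FE stack: mm, MPa, N. Effective strain is dimensionless.
- Binarisation is inclusive (`values ≥ τ`).
- `register_translation(moving, fixed)` returns the offset that aligns
  `moving` to `fixed` via `apply_offset(moving, offset)`.
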