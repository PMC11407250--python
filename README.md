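# fetaldot

Sensitivity analysis for transabdominal fetal pulse oximetry on synthetic
maternal–fetal phantoms.

The package builds layered abdominal phantoms with an embedded fetal head
(fat → muscle/uterus → amniotic fluid → scalp/skull/CSF/brain), solves the
continuous-wave diffusion equation with P1 finite elements, and analyses how
well a source–detector (SD) grid on the abdominal surface can measure and
reconstruct fetal-brain absorption changes:

- **phantom** — structured tetrahedral phantom generator, 6×6 optode grids,
  channel selection (20–120 mm) and distance grouping (20 mm bins);
- **optics** — chromophore-based absorption (HbO/Hb/water/fat/melanin),
  power-law scattering, systolic/diastolic fetal states (arterial volume
  pulse, Vp = 5%);
- **forward** — CW diffusion FEM (Robin boundary, point sources one
  transport mean free path deep, 10×10 mm large-detector patches);
- **sensitivity** — adjoint absorption Jacobians, per-group total
  normalized sensitivity maps, fetal-brain channel ranking;
- **flatfield** — uniform 1% µa perturbation, noisy difference data, and
  Moore–Penrose reconstruction with spatially variant regularization;
- **pulse_noise** — ΔOD, detector dynamic range, and the
  distance-dependent noise model k(r) = 0.0024·e^(0.0236·r) with
  480-repetition averaging;
- **pipeline_cli** — YAML-configured end-to-end runs with checksummed,
  plain-text outputs (CSV/JSON/ASCII-VTU).

## CLI

```bash
fetaldot phantom build --config configs/example.yaml --outdir out/
fetaldot run --config configs/example.yaml --outdir out/ --seed 1
fetaldot run --config configs/example.yaml --wavelengths 730,810 --no-noise
fetaldot summarize --outdir out/
fetaldot report --outdir out/
```

A run writes `channels.csv`, `metrics.csv` (per-channel Φ, ΔOD, dynamic
range, clean and noisy), `rankings.csv` (top-10 brain-sensitive channels per
wavelength × SD group), `summary.csv` (group mean ± std of the five panel
quantities), `feasibility.json` (rule-of-thumb thresholds: normalized
Jacobian > 1%, flat field in the 1–10% band), `layout.json`, and
`manifest.json` (config echo, stage timings, SHA-256 of every output).
`--export-fields` in the config (`export_fields: true`) additionally writes
labeled meshes and sensitivity maps as ASCII `.vtu`.

## Notes

- Meshes are structured five-tet-per-cell lattices chosen for their mirror
  symmetry (chiral decompositions showed direction-dependent decay that
  breaks source–detector reciprocity checks on coarse grids).
- Absorption mass and boundary terms are lumped, which makes the FEM system
  an M-matrix: fluence solutions are strictly positive and absorption
  Jacobian entries are non-positive by construction.
- All outputs are plain text; binary/scratch artifacts belong in `scratch/`.
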