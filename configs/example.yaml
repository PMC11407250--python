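# Coarse maternal-fetal phantom run: shallow (OA-like) geometry, two
# wavelengths, full analysis chain.  All lengths in mm.
phantom:
  fat_thickness: 10.0
  muscle_thickness: 10.0
  fluid_gap: 4.0
  fetal_head_radius: 45.0
  scalp_thickness: 2.0
  skull_thickness: 2.0
  csf_thickness: 2.0
  lateral_extent: [170.0, 140.0]
  target_edge_length: 5.0
wavelengths: [730.0, 810.0]
grid_shape: [6, 6]
grid_extent: [100.0, 70.0]
channel_min_distance: 20.0
channel_max_distance: 120.0
bin_edges: [20.0, 40.0, 60.0, 80.0, 100.0, 120.0]
detector_side: 10.0
patch_spacing: 0.4
noise:
  amplitude: 0.0024
  rate: 0.0236
  repetitions: 480
use_noise: true
top_k: 10
export_fields: false
seed: 0
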