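# Per-modality processing of a phantom sample, ending in fusion and
# clustering.  Generate the inputs first:
#   hsifuse phantom --seed 42 --scale 0.2 --out phantom/
# then:
#   hsifuse run --workflow examples/workflow.yaml --out results/
version: 1
seed: 42
datasets:
  nir: phantom/nir.h5
  mir: phantom/mir.h5
  rgb: phantom/rgb.h5
steps:
  # MIR: reference modality
  - {op: correct_vignette, inputs: [mir], params: {sigma: 10, epsilon: 5}}
  - {op: remove_background, inputs: [mir]}
  - {op: minmax_normalize, inputs: [mir], params: {per: band}}
  - {op: register_layers_keypoint, inputs: [mir]}
  # NIR
  - {op: reference_correct, inputs: [nir], params: {reference_csv: phantom/reference_nir.csv}}
  - {op: remove_spikes, inputs: [nir]}
  - {op: remove_background, inputs: [nir]}
  - {op: minmax_normalize, inputs: [nir], params: {per: spectrum}}
  - {op: spa_select_bands, inputs: [nir], params: {k: 20}}
  - {op: resize_cube, inputs: [nir], params: {match: mir}}
  - {op: align_ecc, inputs: [nir], params: {reference: mir}}
  # RGB
  - {op: correct_vignette, inputs: [rgb], params: {sigma: 100, epsilon: 5}}
  - {op: remove_background, inputs: [rgb]}
  - {op: minmax_normalize, inputs: [rgb], params: {per: spectrum}}
  - {op: resize_cube, inputs: [rgb], params: {match: mir}}
  - {op: align_ecc, inputs: [rgb], params: {reference: mir}}
  # fusion + clustering
  - {op: fuse_cubes, inputs: [nir, mir, rgb], output: fused}
  - {op: minibatch_kmeans, inputs: [fused], output: labels, params: {k: 9}}
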