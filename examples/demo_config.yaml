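# Reduced demo geometry: the full pipeline in about a minute.
# For the reference geometry use n_rois: 90, fs_acquisition: 1024,
# epoch_length: 8.0, n_epochs: 10, target_fs: 512, n_perm: 10000.
cohort:
  n_patients: 10
  n_controls: 10
  n_rois: 20
  fs_acquisition: 256.0
  epoch_length: 2.0
  n_epochs: 5
  carrier_band: [13.0, 30.0]
  coupling_graph_patients: {topology: chain, strength: 0.8}
  coupling_graph_controls: {topology: star, strength: 0.8}
  noise_sd: 1.0
epoch_length: 2.0
n_epochs: 5
target_fs: null
n_perm: 1000
alpha: 0.05
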