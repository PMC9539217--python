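# Demo run: a 40-tree five-species synthetic stand, full pipeline.
# canopyfuse run-all --config examples/demo.yaml --verbose
out_dir: demo_run
seed: 12
scene:
  extent: [42.0, 42.0]
  n_trees: 40
  point_density: 100.0
segmentation:
  min_points: 40
selection:
  n_trees_rf: 200
classification:
  n_repetitions: 10
  k_max: 30
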