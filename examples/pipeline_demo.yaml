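# End-to-end demo: 2 control cells calibrate the crosstalk K, then 3
# dimerizing cells are fitted and compared with the random-pairing model.
#   dimerscope run --config examples/pipeline_demo.yaml --out demo_out/
seed: 11
mode: fccs
geometry:
  omega_g: 0.222
  omega_r: 0.272
  r0: 0.125
acquisition:
  duration: 30.0
  dt: 0.0005
  box_size: 3.0
  segment_length: 10.0
control:
  n_cells: 2
  c_g: 80.0
  c_r: 60.0
  d_g: 0.41
  d_r: 0.41
  k_crosstalk: 0.05
measurement:
  n_cells: 3
  c_g: 12.5
  c_r: 12.5
  c_gr: 25.0
  d_g: 0.235
  d_r: 0.235
  d_gr: 0.235
  x_g: 2
  x_r: 2
  k_crosstalk: 0.05
x: 2
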