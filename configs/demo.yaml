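# Two-organ demo: simulated dehydration experiment for maple petiole and
# stem, 10 plants each, fitted and compared at psi50.
seed: 42
out_dir: xylemct_out
n_boot: 300
organs:
  - preset: maple_petiole
    n_plants: 10
    psi_min: -4.0
    psi_max: -0.2
    image_size_px: [400, 400]
  - preset: maple_stem
    n_plants: 10
    psi_min: -5.0
    psi_max: -0.2
    image_size_px: [400, 400]
segmentation:
  method: fixed
  threshold: 0.30
compare:
  - [maple_petiole, maple_stem, psi50]
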