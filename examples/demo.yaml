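simulation:
  regions:
    - {name: CTRL, length: 12000, diploid_copy_number: 2, snv_density: 2.5}
    - {name: DEFB, length: 8000, diploid_copy_number: 6, snv_density: 2.0, htcr_fraction: 0.3}
  target_depth_per_copy: 20.0
  seed: 17
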