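# Flattened 6 MV beam line preset.
# The flattening filter is designed at load/run time by
# linacmc.head.design_flattening_filter (HeadConfig.ensure_filter()).
source:
  mean_energy: 7.5        # MeV
  energy_spread_sigma: 0.4  # MeV
  spot_fwhm_mm: 1.0
head:
  mode: flat
  field_size_cm: 10.0
  ssd: 100.0
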