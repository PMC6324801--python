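# Flattening-filter-free 7 MV beam line preset.
# Primary electron source accepted by the commissioning procedure.
source:
  mean_energy: 8.8        # MeV
  energy_spread_sigma: 0.4  # MeV
  spot_fwhm_mm: 1.0
head:
  mode: fff
  field_size_cm: 10.0
  ssd: 100.0
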