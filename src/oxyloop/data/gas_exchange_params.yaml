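# Three-compartment oxygen-exchange parameters (alveolar air / lung tissue /
# capillary blood). Volumes in litres, sigma converts partial pressure to molar
# concentration (M/mm), diffusion rates in L/s.
# Transcription notes: the source table prints the tissue solubility under a
# duplicated alveolar label and the tissue->blood diffusion rate under a duplicated
# tissue->air label; they are corrected here to sigma_T and D_TB. D_TB is printed as
# a range (6.7-10)e-12; the mid-range 8.0e-12 is the point default.
gas_exchange:
  V_A: 1.9e-7
  V_T: 4.2e-8
  V_B: 7.5e-9
  sigma_A: 2.5e-5
  sigma_T: 1.2e-6
  sigma_B: 1.2e-6
  D_TA: 2.4e-12
  D_TB: 8.0e-12
  D_TB_range: [6.7e-12, 1.0e-11]
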