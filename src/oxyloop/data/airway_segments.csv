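# Lumped R/L/C of the four airway sections used in the second-order section models
# 1/(LC s^2 + RC s + 1), with the source's own RC and LC product columns.
# Units: R in cm H2O/(L/s), L in cm H2O/(L/s^2), C in L/cm H2O.
# Transcription notes carried as printed: nasal RC product of the printed factors is
# 16.3327*0.132 = 2.1559 while the canonical nasal equation uses 2.165 (0.4% apart);
# bronchi LC is printed 1.44e-5 while R*L*C column arithmetic gives 1.35e-5 -- the
# printed 1.44e-5 is canonical.
section,R,L,C,RC,LC
nasal,16.3327,0.02,0.132,2.156,0.0027
trachea,0.086,0.0059,0.0631,0.0054,0.00037
bronchi,0.0087,0.0002929,0.0461,0.000402,1.44e-5
alveoli,0.00055,6.47e-8,1.0396,0.000571,6.72e-8
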