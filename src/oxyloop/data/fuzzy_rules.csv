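# 25-rule Mamdani rule base mapping (model-following error e, error increment de)
# to the adaptation gain m. Rows are e labels, columns are de labels.
# The PM/PB rows are deliberately not mirror images of the NM/NB rows; the
# asymmetry is part of the published rule base and is shipped verbatim.
e,NB,NM,ZE,PM,PB
NB,NB,NB,NB,NM,ZE
NM,NB,NB,NM,ZE,PM
ZE,NB,NM,ZE,PM,PB
PM,PM,PM,PM,PB,PB
PB,PM,PM,PB,PB,PB
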