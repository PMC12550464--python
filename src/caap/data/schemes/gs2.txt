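# Six classes by polarity and side-chain volume.
C
AGV
ILMP
FWY
STNQH
DEKR
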