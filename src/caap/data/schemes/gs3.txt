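# Seven classes; small neutral residues (A,G,P,S,T) form one class.
AGPST
DE
KRH
NQ
C
ILMV
FWY
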