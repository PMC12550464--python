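# Twelve fine-grained classes: only highly similar side chains share a class.
G
AILV
P
C
M
ST
NQ
DE
KRH
F
Y
W
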