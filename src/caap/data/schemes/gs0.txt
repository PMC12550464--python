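# Randomised control partition: the 20 residues shuffled between six classes.
# One class per line, residues concatenated.
GWDC
PM
K
IQLS
EATVYF
NHR
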