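gene	gdi_score
FLNB	6.2
TTN	42.9
TBC1D2	9.7
TOX2	4.4
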