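F8A1
CCZ1
GMCL1
RAB13
RAB19
RAB41
RAB43
RAB44
RAB6C
RAB7B
RAB9B
REP15
RPH3A
TBC1D3B
YWHAQ
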