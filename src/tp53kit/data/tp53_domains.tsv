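name	start	end
TAD1	1	42
TAD2	43	63
PRR	64	92
DBD	102	292
L2	163	195
L3	236	251
TET	323	356
REG	364	393
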