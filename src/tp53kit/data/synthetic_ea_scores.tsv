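# SYNTHETIC evolutionary-action scores for demonstration and testing only.
# Real EAp53 scores come from the external EAp53 server and are supplied by
# the user as an input table; the values below are placeholders chosen to
# span the 75-point risk threshold for the recurrent NSCLC hotspots.
ref	pos	alt	score
R	110	L	55.0
R	158	L	78.1
R	175	H	91.4
Y	220	C	68.2
Y	236	C	81.5
G	245	S	89.0
R	248	Q	90.7
R	249	S	93.2
R	273	C	88.4
R	280	K	72.6
R	282	W	92.3
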