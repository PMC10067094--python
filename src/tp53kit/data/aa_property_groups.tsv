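residue	group
G	nonpolar
A	nonpolar
V	nonpolar
L	nonpolar
I	nonpolar
P	nonpolar
F	nonpolar
M	nonpolar
W	nonpolar
S	polar_uncharged
T	polar_uncharged
C	polar_uncharged
Y	polar_uncharged
N	polar_uncharged
Q	polar_uncharged
K	positive
R	positive
H	positive
D	negative
E	negative
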