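exon	first_codon	last_codon
2	1	25
3	26	32
4	33	125
5	126	187
6	188	224
7	225	261
8	262	307
9	308	331
10	332	367
11	368	393
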