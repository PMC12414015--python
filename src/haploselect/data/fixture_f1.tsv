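block_id	individual_id	copy	variant_id	value
0	ind1	1	0	4.0
0	ind1	2	0	4.0
0	ind2	1	1	3.0
0	ind2	2	2	1.0
0	ind3	1	0	4.0
0	ind3	2	1	3.0
0	ind4	1	3	5.0
0	ind4	2	2	1.0
1	ind1	1	0	2.0
1	ind1	2	1	0.0
1	ind2	1	0	2.0
1	ind2	2	0	2.0
1	ind3	1	2	6.0
1	ind3	2	1	0.0
1	ind4	1	1	0.0
1	ind4	2	1	0.0
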