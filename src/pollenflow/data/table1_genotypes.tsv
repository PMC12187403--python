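locus	741	814	816	842	849	A4	A16	A29	A38	A203	Daddow	Own Venture
27718	TT	GG	GG	GG	GG	GG	GG	GT	GT	GG	GG	GG
52998	AA	CC	CC	CC	CC	CC	CC	CT	CT	CC	CC	CC
3756	CC	TT	CC	CC	CC	CC	CC	CC	CC	CC	CC	CC
10725	TT	TC	CC	TT	TT	TT	TT	TT	TT	TT	TT	TT
10814	AA	AA	AA	GG	AA	AA	AA	AA	AA	AA	AA	AA
13501	GG	GG	GG	NA	TT	GG	GG	GG	GG	GG	GG	GG
74523	GG	GG	NA	GG	TT	GG	GG	GG	GG	GG	GG	GG
24338	GG	GG	GG	GG	GG	AA	GA	GA	GA	GG	GG	GG
8730	GG	GG	GG	GG	GG	TT	GT	GT	GT	GG	GG	GT
71837	CC	CC	CC	CC	CC	CC	GG	CC	CC	CC	CC	CC
3801	CC	CC	CC	CC	CC	CC	CC	TT	CC	CC	CC	CC
78400	GG	GG	GG	GG	GG	GG	GG	GG	AA	GG	GG	GG
88700	CC	CC	CC	CC	CC	CC	CC	CC	GG	CC	CC	CC
1724	TT	TT	TT	TT	TC	TT	TT	TC	TC	CC	TT	TT
14937	AA	AA	AA	AA	AA	AA	AA	AA	AA	AA	GG	AA
47410	TT	TT	TT	TT	TT	TT	TT	TT	TT	TT	TT	CC
60567	AA	AA	AA	AA	AA	AA	AA	AA	AA	AA	AA	TT
86621	CC	CC	CC	CC	CC	CC	CC	CC	CC	CC	CC	TT
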