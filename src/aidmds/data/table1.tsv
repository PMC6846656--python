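group	strand	replicate	denominator	numerator
NTS-control	NTS	1	3469440	110
NTS+PolII	NTS	1	541824	15
NTS+AID	NTS	1	1926144	76
NTS+AID	NTS	2	5186928	191
NTS+AID	NTS	3	6159120	227
NTS+PolII+AID	NTS	1	648576	132
NTS+PolII+AID	NTS	2	4347888	1405
NTS+PolII+AID	NTS	3	4694496	1787
NTS+PolII+AID+DSIF	NTS	1	4221600	2400
NTS+PolII+AID+DSIF	NTS	2	4561776	2310
TS-control	TS	1	5574690	180
TS+PolII	TS	1	1922052	49
TS+AID	TS	1	3291222	192
TS+AID	TS	2	9993060	593
TS+AID	TS	3	5402298	228
TS+PolII+AID	TS	1	2713590	1573
TS+PolII+AID	TS	2	6243336	2632
TS+PolII+AID	TS	3	4165854	1672
TS+PolII+AID+DSIF	TS	1	5415564	1719
TS+PolII+AID+DSIF	TS	2	4594854	1721
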