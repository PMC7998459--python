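species	core	name	formula	theoretical_mz	measured_mz	delta_ppm
A_subjunquillea	TFLPPLFVPP	CylG1	C59H84N10O11	1109.6394	1109.6398	0.36
A_subjunquillea	AFFPPFFIPP	CylG2	C65H80N10O10	1161.6132	1161.6161	2.50
A_rimosa	ISDPTAYP	CylH1	C39H56N8O13	845.4039	845.4040	0.12
A_rimosa	FIPLGIITILP	CylH2	C61H99N11O12	1178.7547	1178.7555	0.68
A_rimosa	FPTRPVFP	CylH3	C48H67N11O9	942.5196	942.5191	0.53
A_pallidorosea	EFIVFGIFP	CylI1	C56H75N9O11	1050.5658	1050.5694	3.43
A_pallidorosea	FVIIPPFIFP	CylI2	C65H90N10O10	1171.6914	1171.6941	2.31
A_pallidorosea	YFFNDHPP	CylI3	C51H59N11O12	1018.4417	1018.4421	0.39
A_pallidorosea	TIHLFSAP	CylI4	C42H62N10O10	867.4723	867.4733	1.15
A_pallidorosea	MHILAPPP	CylI5	C41H64N10O8S	857.4702	857.4714	1.40
A_exitialis	FVFVASPP	CylJ1	C44H60N8O9	845.4556	845.4582	3.08
A_exitialis	LFFPPDFRPP	CylJ2	C63H83N13O12	1214.6357	1214.6357	0.00
A_exitialis	VFSLPVFFP	amanexitide	C56H75N9O10	1034.5709	1034.5734	2.42
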