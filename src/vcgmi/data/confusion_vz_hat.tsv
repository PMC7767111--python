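	AMI	ALMI	ASMI	ASLMI	IMI	ILMI	IPMI	IPLMI	LMI	PMI	PLMI	HC
AMI	2228	74	272	1	76	24	8	14	5	6	9	83
ALMI	45	2245	96	0	38	11	18	7	1	2	1	70
ASMI	103	76	3591	2	105	87	4	13	0	0	0	133
ASLMI	0	0	0	134	0	0	0	0	0	0	0	0
IMI	147	94	186	0	3379	254	18	80	14	3	28	366
ILMI	18	17	35	0	202	2619	2	109	11	2	10	118
IPMI	7	3	1	0	5	5	313	1	0	0	0	1
IPLMI	3	2	3	0	137	31	3	870	0	0	0	14
LMI	0	0	0	0	2	0	0	1	156	0	0	0
PMI	0	0	0	0	0	0	0	0	0	137	0	0
PLMI	0	0	0	0	0	0	0	6	3	0	279	0
HC	212	77	82	0	311	448	3	184	8	15	6	5457
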