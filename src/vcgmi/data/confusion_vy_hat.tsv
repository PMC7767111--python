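	AMI	ALMI	ASMI	ASLMI	IMI	ILMI	IPMI	IPLMI	LMI	PMI	PLMI	HC
AMI	2232	44	113	0	137	55	4	32	5	32	4	142
ALMI	35	2207	49	15	87	25	3	9	0	34	1	69
ASMI	161	78	3111	9	176	103	12	25	0	0	36	403
ASLMI	0	1	0	132	0	0	0	0	0	0	1	0
IMI	95	116	157	2	3702	136	6	72	12	2	38	231
ILMI	8	15	50	1	130	2645	4	21	26	0	3	240
IPMI	3	0	4	0	5	1	319	0	0	0	0	4
IPLMI	26	7	5	0	43	27	2	939	2	1	0	11
LMI	0	0	0	0	0	0	0	0	159	0	0	0
PMI	0	0	0	0	0	0	0	0	0	137	0	0
PLMI	0	1	0	0	0	2	0	0	0	0	285	0
HC	217	276	289	0	252	244	10	40	37	58	6	5374
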