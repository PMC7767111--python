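	AMI	ALMI	ASMI	ASLMI	IMI	ILMI	IPMI	IPLMI	LMI	PMI	PLMI	HC
AMI	1453	255	150	0	335	228	21	97	44	2	39	176
ALMI	154	1295	219	54	228	141	37	57	2	128	129	90
ASMI	273	217	1563	25	605	555	41	101	129	10	125	470
ASLMI	0	0	0	134	0	0	0	0	0	0	0	0
IMI	219	279	404	65	1748	372	72	144	51	35	177	1003
ILMI	173	82	113	0	281	1723	26	204	122	3	5	411
IPMI	5	8	3	0	9	0	310	0	0	0	0	1
IPLMI	31	68	77	1	84	155	2	449	53	1	19	123
LMI	2	0	0	0	0	1	0	0	156	0	0	0
PMI	0	0	0	0	0	0	0	0	0	137	0	0
PLMI	0	1	1	0	7	3	0	5	0	0	261	10
HC	260	111	322	11	618	726	12	356	87	20	281	3999
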