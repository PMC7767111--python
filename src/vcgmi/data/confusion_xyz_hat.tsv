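	AMI	ALMI	ASMI	ASLMI	IMI	ILMI	IPMI	IPLMI	LMI	PMI	PLMI	HC
AMI	2762	5	9	0	7	4	0	1	0	0	3	9
ALMI	10	2504	6	0	2	2	2	0	1	0	0	7
ASMI	9	12	4078	1	6	2	3	3	0	0	0	0
ASLMI	0	0	0	134	0	0	0	0	0	0	0	0
IMI	5	3	4	0	4528	11	1	7	0	0	4	6
ILMI	3	3	8	0	3	3119	1	1	1	0	1	3
IPMI	3	0	0	0	3	0	329	0	0	0	0	1
IPLMI	2	3	3	0	6	8	0	1039	0	1	0	1
LMI	0	0	0	0	0	0	0	0	159	0	0	0
PMI	0	0	0	0	0	0	0	0	0	137	0	0
PLMI	0	0	0	0	0	0	0	1	0	0	287	0
HC	2	2	4	0	10	1	1	1	0	1	0	6781
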