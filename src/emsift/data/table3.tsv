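chromosome	R2	R3	R4	R5	R6	R7	R8	R9	R10
Chr02	6	5	1	4	2	0	1	8	7
Chr04	7	4	0	11	5	3	3	5	3
Chr07	11	6	4	12	3	2	2	10	4
Chr08	3	1	0	5	1	0	0	4	4
Chr10	3	3	0	11	0	1	4	2	1
Chr12	8	3	0	3	5	0	3	4	7
Chr13	3	2	1	2	0	0	1	0	1
Chr14	2	2	1	0	3	1	1	2	4
Chr15	6	3	1	2	2	2	1	3	5
Chr01	8	6	4	11	3	1	1	15	6
Chr03	9	6	1	3	0	0	2	5	3
Chr05	9	5	1	6	3	2	0	3	5
Chr06	7	3	0	16	1	1	0	3	1
Chr09	2	1	1	2	2	0	1	0	2
Chr11	13	7	0	4	3	0	1	3	3
Chr16	7	4	2	5	5	1	3	4	4
Chr17	3	2	1	6	5	0	2	5	11
Chr18	6	0	0	2	1	1	0	2	1
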