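chromosome	R2	R3	R4	R5	R6	R7	R8	R9	R10
Chr02	121	116	4	133	55	7	30	133	110
Chr04	156	91	7	227	56	16	18	102	51
Chr07	330	129	122	282	110	25	34	207	110
Chr08	88	85	15	84	40	3	12	130	70
Chr10	109	68	4	248	33	12	21	124	45
Chr12	151	99	62	117	56	14	13	87	72
Chr13	69	89	22	60	13	6	5	55	22
Chr14	121	41	33	45	43	7	16	63	70
Chr15	132	73	11	91	95	12	23	136	51
Chr01	248	119	83	213	91	21	48	266	145
Chr03	156	90	5	67	36	12	23	98	107
Chr05	161	97	15	218	57	11	19	32	78
Chr06	137	62	6	148	33	7	13	72	65
Chr09	34	42	4	79	10	6	17	33	24
Chr11	207	104	17	245	59	7	19	102	52
Chr16	135	42	60	135	84	6	32	169	104
Chr17	130	42	23	131	66	12	24	90	90
Chr18	73	12	23	76	28	7	11	55	28
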