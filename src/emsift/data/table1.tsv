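chromosome	R2	R3	R4	R5	R6	R7	R8	R9	R10
Chr02	138.0	79.6	3.3	189.1	66.6	8.7	21.7	285.4	93.2
Chr04	218.0	65.1	11.5	366.7	65.4	2.7	13.1	73.3	28.3
Chr07	210.5	81.3	59.8	164.2	82.6	3.6	13.9	103.4	33.3
Chr08	156.8	252.8	33.8	125.0	66.0	3.9	14.0	244.8	53.8
Chr10	172.9	203.3	5.0	316.1	16.5	2.6	13.1	71.9	23.6
Chr12	110.0	100.8	168.9	95.8	62.4	3.4	12.9	139.5	70.0
Chr13	268.8	203.4	50.7	142.2	45.5	9.6	11.4	115.1	25.6
Chr14	169.4	32.3	64.7	71.9	67.6	2.8	11.7	109.4	140.1
Chr15	113.3	33.1	6.5	88.3	109.8	1.9	11.2	98.4	22.3
Chr01	238.4	85.1	54.6	172.3	40.6	3.1	14.1	164.2	68.5
Chr03	205.3	97.9	5.7	74.6	24.6	7.3	20.4	81.2	70.1
Chr05	313.8	201.3	9.9	309.1	69.3	3.1	15.8	21.3	63.4
Chr06	366.6	97.7	8.4	396.0	39.9	3.4	14.9	63.0	76.2
Chr09	65.3	83.2	11.7	171.7	13.9	4.7	11.3	66.9	21.9
Chr11	363.8	351.9	15.1	244.2	140.9	4.1	17.4	70.9	38.8
Chr16	149.8	27.9	22.1	129.6	104.0	2.5	14.2	304.8	118.2
Chr17	142.7	22.4	28.0	275.8	146.7	9.8	23.4	138.2	126.4
Chr18	260.2	21.3	23.5	209.8	46.4	4.3	14.8	129.8	25.0
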