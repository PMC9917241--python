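set_label	id	quasi_smiles	endpoint	calculated
C	1	O=[Al]O[Al]=O[c25,00]	102.7800	134.3224
V	2	O=[Al]O[Al]=O[c50,00]	103.4400	126.9137
V	3	O=[Al]O[Al]=O[c100,00]	99.8800	116.2402
A	4	O=[Al]O[Al]=O[c200,00]	93.2600	109.9123
P	5	O=[Bi]O[Bi]=O[c25,00]	98.6300	112.2648
A	6	O=[Bi]O[Bi]=O[c50,00]	100.7300	104.8562
A	7	O=[Bi]O[Bi]=O[c100,00]	99.6300	94.1827
A	8	O=[Bi]O[Bi]=O[c200,00]	100.2600	87.8548
P	9	O=[Ge]=O[c25,00]	97.8300	85.6033
P	10	O=[Ge]=O[c50,00]	100.1900	78.1946
P	11	O=[Ge]=O[c100,00]	99.5000	67.5211
P	12	O=[Ge]=O[c200,00]	96.7000	61.1932
C	13	[Co]=O[c25,00]	54.4100	52.4457
P	14	[Co]=O[c50,00]	15.5500	45.0370
P	15	[Co]=O[c100,00]	5.6600	34.3635
A	16	[Co]=O[c200,00]	3.2600	28.0356
A	17	[Co]=O.O=[Co]O[Co]=O[c25,00]	95.4400	61.3872
P	18	[Co]=O.O=[Co]O[Co]=O[c50,00]	84.9300	53.9786
C	19	[Co]=O.O=[Co]O[Co]=O[c100,00]	49.9600	43.3051
V	20	[Co]=O.O=[Co]O[Co]=O[c200,00]	22.6500	36.9772
P	21	O=[Cr]O[Cr]=O[c25,00]	101.7700	89.0326
P	22	O=[Cr]O[Cr]=O[c50,00]	94.8500	81.6240
V	23	O=[Cr]O[Cr]=O[c100,00]	65.8100	70.9505
C	24	O=[Cr]O[Cr]=O[c200,00]	46.3600	64.6226
A	25	[Cu]=O[c25,00]	99.1700	45.0965
V	26	[Cu]=O[c50,00]	60.4100	37.6879
A	27	[Cu]=O[c100,00]	19.8700	27.0144
P	28	[Cu]=O[c200,00]	0.1000	20.6865
C	29	O=[Dy]O[Dy]=O[c25,00]	97.6000	109.6235
A	30	O=[Dy]O[Dy]=O[c50,00]	104.1500	102.2148
C	31	O=[Dy]O[Dy]=O[c100,00]	95.0600	91.5413
V	32	O=[Dy]O[Dy]=O[c200,00]	89.7000	85.2134
C	33	O=[Er]O[Er]=O[c25,00]	100.1600	89.0326
V	34	O=[Er]O[Er]=O[c50,00]	96.5800	81.6240
P	35	O=[Er]O[Er]=O[c100,00]	95.1000	70.9505
P	36	O=[Er]O[Er]=O[c200,00]	89.7400	64.6226
V	37	O=[Eu]O[Eu]=O[c25,00]	99.4800	106.8651
P	38	O=[Eu]O[Eu]=O[c50,00]	99.9800	99.4564
A	39	O=[Eu]O[Eu]=O[c100,00]	95.7800	88.7829
V	40	O=[Eu]O[Eu]=O[c200,00]	86.5300	82.4550
C	41	[Fe+3].[Fe+3].[O-2].[O-2].[O-2][c25,00]	99.9200	108.3871
C	42	[Fe+3].[Fe+3].[O-2].[O-2].[O-2][c50,00]	98.8800	100.9784
C	43	[Fe+3].[Fe+3].[O-2].[O-2].[O-2][c100,00]	97.3700	90.3049
C	44	[Fe+3].[Fe+3].[O-2].[O-2].[O-2][c200,00]	99.9200	83.9770
C	45	[Fe]=O.O=[Fe]O[Fe]=O[c25,00]	95.6700	112.7077
P	46	[Fe]=O.O=[Fe]O[Fe]=O[c50,00]	100.6200	105.2991
A	47	[Fe]=O.O=[Fe]O[Fe]=O[c100,00]	97.5800	94.6256
C	48	[Fe]=O.O=[Fe]O[Fe]=O[c200,00]	99.0300	88.2977
V	49	[Gd+3].[Gd+3].[O-2].[O-2].[O-2][c25,00]	100.3700	108.3871
V	50	[Gd+3].[Gd+3].[O-2].[O-2].[O-2][c50,00]	98.1200	100.9784
P	51	[Gd+3].[Gd+3].[O-2].[O-2].[O-2][c100,00]	94.3400	90.3049
V	52	[Gd+3].[Gd+3].[O-2].[O-2].[O-2][c200,00]	86.9100	83.9770
C	53	O=[Hf]=O[c25,00]	100.2900	85.6033
P	54	O=[Hf]=O[c50,00]	102.6100	78.1946
P	55	O=[Hf]=O[c100,00]	101.7900	67.5211
P	56	O=[Hf]=O[c200,00]	95.0000	61.1932
V	57	[In+3].[In+3].[O-2].[O-2].[O-2][c25,00]	100.6200	106.6455
C	58	[In+3].[In+3].[O-2].[O-2].[O-2][c50,00]	97.9200	99.2368
C	59	[In+3].[In+3].[O-2].[O-2].[O-2][c100,00]	94.2200	88.5633
A	60	[In+3].[In+3].[O-2].[O-2].[O-2][c200,00]	87.9600	82.2354
V	61	[La+3].[La+3].[O-2].[O-2].[O-2][c25,00]	100.7500	108.3871
V	62	[La+3].[La+3].[O-2].[O-2].[O-2][c50,00]	97.5400	100.9784
C	63	[La+3].[La+3].[O-2].[O-2].[O-2][c100,00]	92.7000	90.3049
C	64	[La+3].[La+3].[O-2].[O-2].[O-2][c200,00]	82.8000	83.9770
A	65	O=[Mn]=O[c25,00]	48.8900	55.2509
A	66	O=[Mn]=O[c50,00]	32.7700	47.8423
P	67	O=[Mn]=O[c100,00]	22.0400	37.1688
A	68	O=[Mn]=O[c200,00]	1.7500	30.8409
A	69	O=[Mn]O[Mn]=O[c25,00]	54.9500	28.3280
A	70	O=[Mn]O[Mn]=O[c50,00]	31.5800	20.9193
A	71	O=[Mn]O[Mn]=O[c100,00]	11.1200	10.2458
V	72	O=[Mn]O[Mn]=O[c200,00]	5.1400	3.9179
C	73	O=[Nd]O[Nd]=O[c25,00]	100.2400	110.9428
A	74	O=[Nd]O[Nd]=O[c50,00]	100.3200	103.5342
P	75	O=[Nd]O[Nd]=O[c100,00]	95.3200	92.8607
P	76	O=[Nd]O[Nd]=O[c200,00]	89.9300	86.5328
P	77	[O-2].[Ni+2][c25,00]	103.3200	112.4964
A	78	[O-2].[Ni+2][c50,00]	102.3000	105.0877
A	79	[O-2].[Ni+2][c100,00]	99.7700	94.4142
A	80	[O-2].[Ni+2][c200,00]	86.6000	88.0863
C	81	[Ni+3].[Ni+3].[O-2].[O-2].[O-2][c25,00]	102.7800	96.5984
P	82	[Ni+3].[Ni+3].[O-2].[O-2].[O-2][c50,00]	103.4400	89.1897
V	83	[Ni+3].[Ni+3].[O-2].[O-2].[O-2][c100,00]	87.7500	78.5162
A	84	[Ni+3].[Ni+3].[O-2].[O-2].[O-2][c200,00]	45.3300	72.1883
C	85	O=[Sb]O[Sb]=O[c25,00]	99.7200	89.0326
P	86	O=[Sb]O[Sb]=O[c50,00]	99.9100	81.6240
P	87	O=[Sb]O[Sb]=O[c100,00]	99.6800	70.9505
P	88	O=[Sb]O[Sb]=O[c200,00]	98.8300	64.6226
V	89	O=[Sm]O[Sm]=O[c25,00]	99.6700	115.8481
A	90	O=[Sm]O[Sm]=O[c50,00]	101.1200	108.4395
V	91	O=[Sm]O[Sm]=O[c100,00]	94.0300	97.7660
V	92	O=[Sm]O[Sm]=O[c200,00]	86.9700	91.4381
C	93	O=[Sn]=O[c25,00]	98.8000	111.6224
C	94	O=[Sn]=O[c50,00]	103.5400	104.2137
V	95	O=[Sn]=O[c100,00]	98.7200	93.5402
A	96	O=[Sn]=O[c200,00]	95.1500	87.2123
V	97	O=[Ti]=O[c25,00]	101.2200	85.6033
V	98	O=[Ti]=O[c50,00]	100.2700	78.1946
C	99	O=[Ti]=O[c100,00]	99.2700	67.5211
V	100	O=[Ti]=O[c200,00]	99.2300	61.1932
V	101	O=[W](=O)=O[c25,00]	103.8200	102.0069
V	102	O=[W](=O)=O[c50,00]	96.3200	94.5982
V	103	O=[W](=O)=O[c100,00]	103.3000	83.9248
V	104	O=[W](=O)=O[c200,00]	98.2600	77.5969
C	105	O=[Y]O[Y]=O[c25,00]	97.7000	110.9296
V	106	O=[Y]O[Y]=O[c50,00]	98.1200	103.5209
C	107	O=[Y]O[Y]=O[c100,00]	92.8300	92.8474
A	108	O=[Y]O[Y]=O[c200,00]	86.7300	86.5195
C	109	[O-2].[O-2].[O-2].[Yb+3].[Yb+3][c25,00]	106.5900	108.3871
V	110	[O-2].[O-2].[O-2].[Yb+3].[Yb+3][c50,00]	99.1900	100.9784
P	111	[O-2].[O-2].[O-2].[Yb+3].[Yb+3][c100,00]	99.4400	90.3049
P	112	[O-2].[O-2].[O-2].[Yb+3].[Yb+3][c200,00]	92.3800	83.9770
P	113	[Zn]=O[c25,00]	91.8300	80.0461
A	114	[Zn]=O[c50,00]	87.9600	72.6374
V	115	[Zn]=O[c100,00]	47.6400	61.9639
A	116	[Zn]=O[c200,00]	6.7600	55.6360
C	117	O=[Zr]=O[c25,00]	99.6500	115.9612
C	118	O=[Zr]=O[c50,00]	98.4900	108.5525
A	119	O=[Zr]=O[c100,00]	101.0700	97.8790
P	120	O=[Zr]=O[c200,00]	100.0200	91.5511
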