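# Published top-10 GO-Slim biological-process overrepresentation rows per
# constitution type (PANTHER-style output): reference-list count K,
# target-list count k, expected count (2 d.p.), raw p, combined score.
# The expected column obeys expected = n_mapped * K / N with a fixed
# within-group ratio n_mapped/N, which these rows let us calibrate and check.
group	term_name	go_id	reference_count	target_count	expected	p_value	combined_score
SE	Response to xenobiotic stimulus	GO:0009410	40	12	0.37	5.19e-12	205.5949
SE	Drug metabolic process	GO:0017144	127	21	1.19	5.60e-12	342.0589
SE	Response to drug	GO:0042493	81	16	0.76	8.09e-09	252.1907
SE	Terpenoid metabolic process	GO:0006721	11	5	0.10	9.17e-09	63.41361
SE	Isoprenoid metabolic process	GO:0006720	14	5	0.13	4.93e-08	57.00586
SE	Diterpenoid metabolic process	GO:0016101	10	4	0.09	2.56e-07	41.92858
SE	Positive regulation of leukocyte proliferation	GO:0070665	3	2	0.03	3.39e-07	16.30587
SE	Regulation of smooth muscle contraction	GO:0006940	3	2	0.03	3.56e-07	16.26849
SE	Positive regulation of mononuclear cell proliferation	GO:0032946	3	2	0.03	1.14e-06	16.21936
SE	Positive regulation of lymphocyte proliferation	GO:0050671	3	2	0.03	2.53e-06	16.18301
SY	Cellular metabolic process	GO:0044237	1744	84	32.73	7.02e-16	230.1149
SY	Drug metabolic process	GO:0017144	127	23	2.38	5.71e-13	226.2333
SY	Fatty acid metabolic process	GO:0006631	138	20	2.59	2.50e-11	144.3277
SY	Response to chemical	GO:0042221	576	39	10.81	9.88e-10	141.426
SY	Response to xenobiotic stimulus	GO:0009410	40	12	0.75	4.88e-08	123.8619
SY	Cofactor metabolic process	GO:0051186	159	19	2.98	1.32e-07	107.5996
SY	Cellular lipid metabolic process	GO:0044255	294	25	5.52	3.47e-07	103.8276
SY	Carbohydrate metabolic process	GO:0005975	185	20	3.47	5.99e-07	103.5943
SY	Ammonium ion metabolic process	GO:0097164	34	10	0.64	1.28e-06	92.36633
SY	Nitrogen compound metabolic process	GO:0006807	38	10	0.71	1.41e-06	85.06531
TE	Response to chemical	GO:0042221	576	22	4.17	6.11e-07	108.7424
TE	Cholesterol homeostasis	GO:0042632	14	6	0.10	4.00e-06	88.67855
TE	Lipid metabolic process	GO:0006629	120	10	0.87	2.08e-05	73.0932
TE	Lipid homeostasis	GO:0055088	33	6	0.24	1.50e-04	56.52157
TE	Response to stimulus	GO:0050896	1190	26	8.61	1.95e-04	53.73646
TE	Drug metabolic process	GO:0017144	127	9	0.92	1.86e-04	53.41338
TE	Response to xenobiotic stimulus	GO:0009410	40	6	0.29	2.37e-04	51.07916
TE	Steroid metabolic process	GO:0008202	44	6	0.32	3.43e-04	47.94313
TE	Cellular catabolic process	GO:0044248	111	8	0.80	4.72e-04	45.28447
TE	Response to drug	GO:0042493	81	7	0.59	6.04e-04	43.22787
TY	Inorganic anion transport	GO:0015698	44	9	0.19	2.13e-09	164.4011
TY	Mitochondrial electron transport, cytochrome c to oxygen	GO:0006123	185	13	0.79	2.33e-09	159.3545
TY	Nitric oxide biosynthetic process	GO:0006809	54	9	0.23	3.18e-09	152.3056
TY	Sensory perception of sweet taste	GO:0050916	55	9	0.24	3.66e-09	152.0322
TY	Arginine catabolic process	GO:0006527	66	9	0.28	1.01e-08	138.1824
TY	Negative regulation of blood pressure	GO:0045776	10	6	0.04	1.11e-08	137.2376
TY	Regulation of lyase activity	GO:0051339	42	8	0.18	1.12e-08	137.1961
TY	Positive regulation of phosphate metabolic process	GO:0045937	45	8	0.19	1.21e-08	134.0532
TY	Secondary metabolite biosynthetic process	GO:0044550	45	8	0.19	1.36e-08	133.5836
TY	ATP synthesis coupled electron transport	GO:0042773	4072	45	17.45	1.48e-08	131.5255
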