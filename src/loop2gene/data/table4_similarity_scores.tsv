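gene	similarity_score	p_value	fdr
TP53	0.60	3.65E-09	4.00E-06
ESR1	0.54	5.95E-07	1.27E-04
FOXA2	0.57	1.86E-06	1.99E-04
EP300	0.41	8.40E-06	4.27E-04
CTNNB1	0.47	1.35E-05	5.54E-04
PTEN	0.46	1.98E-05	7.05E-04
CCND1	0.49	2.12E-05	7.42E-04
FGFR2	0.44	3.97E-05	1.10E-03
RB1	0.50	8.21E-05	1.91E-03
MYCN	0.44	1.15E-04	2.51E-03
ERBB2	0.39	4.15E-04	6.28E-03
AKT1	0.35	5.24E-04	7.31E-03
ERBB3	0.39	1.12E-03	0.01
MAX	0.31	1.75E-03	0.02
NRIP1	0.32	1.82E-03	0.02
ATM	0.31	2.05E-03	0.02
CHD4	0.34	2.67E-03	0.02
FBXW7	0.38	3.75E-03	0.03
DICER1	0.33	4.44E-03	0.03
KRAS	0.33	9.91E-03	0.05
TAF1	0.27	0.03	0.11
ATR	0.29	0.04	0.13
PIK3R2	0.19	0.06	0.17
POLE	0.26	0.07	0.17
CHD3	0.20	0.14	0.26
TAB3	0.22	0.36	0.45
METTL14	0.21	0.40	0.49
KANSL1	0.09	0.67	0.67
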