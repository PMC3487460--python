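reaction	measured_lb	measured_ub	ijn678_lb	ijn678_ub	isyn731_lb	isyn731_ub
RBC	123.00	132.00	109.02	109.10	102.49	106.33
PGK	219.00	237.00	187.11	187.25	182.70	182.92
13PDG	219.00	237.00	187.11	196.36	182.70	201.96
GAPDH	90.00	99.00	74.98	75.07	73.40	73.50
FBA	53.00	66.00	-0.17	74.85	-0.08	73.17
FBP	53.00	66.00	0.00	74.85	0.00	73.17
PGI	15.00	24.00	0.68	0.73	0.82	0.84
G6PD	12.00	21.00	0.00	0.05	0.00	0.03
6PGL	12.00	21.00	0.00	0.05	0.00	0.03
6PGD	12.00	21.00	0.00	0.05	0.00	0.03
PRK	123.00	132.00	109.02	109.10	106.24	106.32
SBGPL	29.00	43.00	-0.17	74.85	-0.08	73.17
SBP	29.00	43.00	0.00	74.85	0.00	73.17
TAL	-6.00	9.00	-36.74	38.28	-35.93	37.32
TKT1	37.20	37.50	36.57	36.60	36.66	36.79
RPI	35.40	35.70	35.18	35.21	35.82	35.86
TKT2	35.40	35.70	37.25	37.28	36.18	36.23
RPE	75.50	76.20	73.83	73.88	72.01	72.10
PGM	22.90	23.60	26.83	26.95	25.92	29.79
ENO	23.40	23.80	26.84	26.95	25.92	29.79
PYK	7.90	11.10	0.00	13.88	0.00	16.72
PDH	11.50	12.00	0.00	8.97	0.00	13.46
CS	3.00	3.40	2.15	2.21	1.35	1.37
ACONT	3.00	3.40	2.15	2.21	1.35	1.37
ICD	3.00	3.00	2.15	2.21	1.32	1.37
SUCD	0.00	0.40	0.00	0.00	0.00	0.00
FUM	1.70	2.00	-5.44	1.55	-7.26	1.49
MDH	1.90	5.20	5.35	5.61	7.15	7.32
ME1	3.70	6.90	0.00	0.17	0.00	0.08
ME2	3.70	6.90			0.00	0.08
PPC	9.90	13.20	11.74	11.98	12.25	12.37
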