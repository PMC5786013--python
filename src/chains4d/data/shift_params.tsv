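# Synthetic parametric chemical-shift statistics (Gaussian per carbon type).
# Means/SDs follow published BMRB-range averages for aliphatic 13C-1H pairs.
# Columns: amino_acid	atom	mean_c	sd_c	mean_h	sd_h
A	CA	53.14	1.95	4.26	0.44
A	CB	18.96	1.80	1.35	0.26
R	CA	56.79	2.30	4.30	0.46
R	CB	30.66	1.80	1.79	0.27
R	CG	27.20	1.20	1.57	0.27
R	CD	43.16	0.90	3.12	0.24
N	CA	53.53	1.90	4.67	0.37
N	CB	38.66	1.70	2.81	0.31
D	CA	54.68	2.00	4.59	0.32
D	CB	40.88	1.60	2.72	0.29
C	CA	58.20	3.30	4.69	0.57
C	CB	32.80	5.50	2.95	0.45
Q	CA	56.58	2.15	4.27	0.44
Q	CB	29.18	1.80	2.05	0.26
Q	CG	33.78	1.10	2.32	0.28
E	CA	57.33	2.10	4.25	0.41
E	CB	29.99	1.70	2.03	0.21
E	CG	36.11	1.10	2.28	0.21
G	CA	45.36	1.30	3.96	0.37
H	CA	56.51	2.30	4.61	0.44
H	CB	30.28	2.10	3.10	0.35
I	CA	61.60	2.70	4.17	0.57
I	CB	38.63	2.00	1.79	0.29
I	CG1	27.69	1.70	1.27	0.41
I	CG2	17.54	1.40	0.78	0.27
I	CD1	13.44	1.70	0.69	0.28
L	CA	55.65	2.15	4.32	0.47
L	CB	42.27	1.90	1.62	0.34
L	CG	26.79	1.10	1.53	0.33
L	CD1	24.66	1.60	0.76	0.27
L	CD2	24.10	1.70	0.73	0.27
K	CA	56.95	2.20	4.26	0.44
K	CB	32.79	1.80	1.78	0.25
K	CG	24.92	1.10	1.37	0.26
K	CD	28.96	1.10	1.61	0.22
K	CE	41.89	0.80	2.92	0.19
M	CA	56.13	2.20	4.39	0.48
M	CB	32.97	2.20	2.03	0.33
M	CG	32.00	1.20	2.43	0.35
M	CE	17.07	1.60	1.86	0.40
F	CA	58.09	2.60	4.62	0.57
F	CB	39.95	2.10	2.99	0.37
P	CA	63.33	1.50	4.40	0.33
P	CB	31.82	1.20	2.07	0.35
P	CG	27.17	1.10	1.93	0.31
P	CD	50.33	1.00	3.64	0.35
S	CA	58.70	2.10	4.51	0.41
S	CB	63.79	1.50	3.88	0.26
T	CA	62.20	2.60	4.46	0.48
T	CB	69.63	1.60	4.16	0.34
T	CG2	21.53	1.10	1.14	0.23
W	CA	57.69	2.55	4.70	0.52
W	CB	29.97	2.00	3.22	0.36
Y	CA	58.08	2.50	4.63	0.57
Y	CB	39.28	2.20	2.90	0.37
V	CA	62.54	2.85	4.18	0.58
V	CB	32.68	1.80	1.99	0.32
V	CG1	21.40	1.40	0.83	0.27
V	CG2	21.32	1.60	0.81	0.29
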