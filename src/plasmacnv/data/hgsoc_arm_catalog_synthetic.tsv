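# Synthetic recurrent arm-level CNV catalog for high-grade serous ovarian carcinoma.
# Constructed stand-in for the tumor-atlas arm lists this package consumes: 8 recurrently
# gained arms (5 at frequency > 0.5) and 22 recurrently lost arms (18 at frequency > 0.5),
# all with FDR q < 0.25. q-values and frequencies are representative, not recomputed from
# tumor data; edit or replace with a catalog derived from your own reference cohort.
arm	direction	q_value	frequency
3q	gain	1e-08	0.65
8q	gain	1e-10	0.75
12p	gain	1e-06	0.55
20q	gain	1e-09	0.70
20p	gain	1e-04	0.55
1q	gain	0.01	0.45
6p	gain	0.02	0.40
2q	gain	0.05	0.35
4p	loss	0.001	0.55
4q	loss	1e-05	0.65
5q	loss	1e-06	0.60
6q	loss	1e-04	0.60
8p	loss	1e-07	0.65
9p	loss	0.001	0.55
9q	loss	0.002	0.55
13q	loss	1e-08	0.70
14q	loss	1e-04	0.60
15q	loss	1e-05	0.65
16q	loss	1e-04	0.60
17p	loss	1e-10	0.75
17q	loss	1e-06	0.65
18p	loss	0.001	0.55
18q	loss	1e-05	0.65
21q	loss	0.005	0.55
22q	loss	1e-06	0.70
Xp	loss	0.01	0.55
7p	loss	0.05	0.45
11p	loss	0.08	0.40
1p	loss	0.10	0.35
10q	loss	0.15	0.30
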