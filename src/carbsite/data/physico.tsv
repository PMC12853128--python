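# Seven physicochemical properties per standard amino acid (Meiler et al. 2001
# scale values; shipped as an editable stand-in table — swap in your preferred
# scales if needed).  Columns follow the feature-group order used throughout
# the package.
# residue	polarizability	steric	isoelectric_point	hydrophobicity	helix_prob	vdw_volume	sheet_prob
A	0.05	1.28	6.11	0.31	0.42	1.00	0.23
R	0.29	2.34	10.74	-1.01	0.36	6.13	0.25
N	0.13	1.60	6.52	-0.60	0.21	2.95	0.22
D	0.11	1.60	2.95	-0.77	0.25	2.78	0.20
C	0.13	1.77	6.35	1.54	0.17	2.43	0.41
Q	0.18	1.56	5.65	-0.22	0.36	3.95	0.25
E	0.15	1.56	3.09	-0.64	0.42	3.78	0.21
G	0.00	0.00	6.07	0.00	0.13	0.00	0.15
H	0.23	2.99	7.69	0.13	0.27	4.66	0.30
I	0.19	4.19	6.04	1.80	0.30	4.00	0.45
L	0.19	2.59	6.04	1.70	0.39	4.00	0.31
K	0.22	1.89	9.99	-0.99	0.32	4.77	0.27
M	0.22	2.35	5.71	1.23	0.38	4.43	0.32
F	0.29	2.94	5.67	1.79	0.30	5.89	0.38
P	0.00	2.67	6.80	0.72	0.13	2.72	0.34
S	0.06	1.31	5.70	-0.04	0.20	1.60	0.28
T	0.11	3.03	5.60	0.26	0.21	2.60	0.36
W	0.41	3.21	5.94	2.25	0.32	8.08	0.42
Y	0.30	2.94	5.66	0.96	0.25	6.47	0.41
V	0.14	3.67	6.02	1.22	0.27	3.00	0.49
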