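# Per-species short-range interaction parameters for the coarse-grained
# explicit-ion MD energy model.
# sigma: bead diameter in Angstrom (residue values follow the standard
#        coarse-grained IDP bead diameters in common use).
# lam:   stickiness in [0,1] scaling the attractive Lennard-Jones branch of
#        the Ashbaugh-Hatch pair potential.  This column is a
#        hydropathy-style stickiness scale chosen so that arginine is
#        stickier than lysine; it is a stand-in for contact-statistics
#        pair tables, which are not redistributed here.
# charge: elementary charges at pH 7.4; mass in Da.
# "y" is phosphotyrosine; NA/CL/MG are free ions (no stickiness).
species	sigma	lam	charge	mass
A	5.04	0.603	0	71.0788
R	6.56	0.559	1	156.1875
N	5.68	0.589	0	114.1038
D	5.58	0.294	-1	115.0886
C	5.48	0.640	0	103.1388
Q	6.02	0.559	0	128.1307
E	5.92	0.000	-1	129.1155
G	4.50	0.570	0	57.0519
H	6.08	0.763	0	137.1411
I	6.18	0.706	0	113.1594
L	6.18	0.721	0	113.1594
K	6.36	0.382	1	128.1741
M	6.18	0.530	0	131.1926
F	6.36	0.921	0	147.1766
P	5.56	0.740	0	97.1167
S	5.18	0.588	0	87.0782
T	5.62	0.588	0	101.1051
W	6.78	1.000	0	186.2132
Y	6.46	0.897	0	163.1760
V	5.86	0.664	0	99.1326
y	6.80	0.600	-2	243.1559
NA	3.30	0.000	1	22.9898
CL	4.40	0.000	-1	35.4530
MG	3.00	0.000	2	24.3050
X	5.00	0.000	0	100.0000
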