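# Pinned atomic masses and natural isotopic abundances.
# Sources: IUPAC-CIAAW 2013 isotopic compositions; AME2016 atomic masses.
# Columns: element, mass_number, exact_mass_Da, abundance
element	mass_number	mass	abundance
H	1	1.00782503224	0.999885
H	2	2.01410177811	0.000115
C	12	12.0000000000	0.9893
C	13	13.0033548351	0.0107
N	14	14.0030740044	0.99636
N	15	15.0001088989	0.00364
O	16	15.9949146196	0.99757
O	17	16.9991317565	0.00038
O	18	17.9991596129	0.00205
F	19	18.9984031627	1.0
P	31	30.9737619984	1.0
S	32	31.9720711744	0.9499
S	33	32.9714589098	0.0075
S	34	33.9678670040	0.0425
S	36	35.9670807100	0.0001
Na	23	22.9897692820	1.0
Cl	35	34.9688527100	0.7576
Cl	37	36.9659026000	0.2424
K	39	38.9637064864	0.932581
K	40	39.9639981660	0.000117
K	41	40.9618252579	0.067302
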