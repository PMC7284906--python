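# Target-compound fingerprint panel: 5-fluorouracil, five of its
# metabolites, and the two co-monitored endogenous nucleotides.
# precursor_mz is the fingerprint [M-H]- value used for extraction and as
# the SIM window center; catalog_mz is the value printed in the original
# inclusion-list catalog, retained for provenance (for FdUMP and FdURD the
# catalog entries 325.0211/245.0605 disagree with both the exact-mass
# computation and the catalog's own scan-filter centers by ~10 ppm and are
# treated as typographical; the fingerprint values are authoritative).
# expected_rt in minutes; empty = not observed (compound not detected).
# fragments: semicolon-separated fragment m/z fingerprint.
# endogenous: 1 = present regardless of drug treatment (no control veto).
name	formula	adduct	precursor_mz	catalog_mz	expected_rt	fragments	endogenous
5-FU	C4H3FN2O2	[M-H]-	129.0100	129.0109	1.6	58.993	0
FdUMP	C9H12FN2O8P	[M-H]-	325.0240	325.0211	1.4	195.006;129.01;96.969;78.959	0
FURD	C9H11FN2O6	[M-H]-	261.0520	261.0529	1.9	171.021;129.009;108.009;84.025	0
FdURD	C9H11FN2O5	[M-H]-	245.0570	245.0605	2.1	155.025;129.009;112.0204	0
FUTP	C9H14FN2O15P3	[M-H]-	500.9510	500.9517		482.9407;158.900;129.01	0
FdUTP	C9H14FN2O14P3	[M-H]-	484.9560	484.956		441.9506;256.80;129.01	0
dUMP	C9H13N2O8P	[M-H]-	307.0330	307.0338	1.4	195.006;111.02;96.9696	1
TMP	C10H15N2O8P	[M-H]-	321.0480	321.0497	1.5	195.005;125.0355;96.9691	1
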