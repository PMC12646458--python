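# Published conformational reporters for the deposited YbbAP models.
# model: "apo" = nucleotide-free (PDB 9GE6), "bound" = AMP-PNP-bound (PDB 9GE7).
# Chains A/B denote the two copies of the ATP-binding cassette (YbbA) and C the
# transmembrane subunit (YbbP); residue numbers follow author numbering.
# Which YbbA copy hosts each half of the Ser50-Ser148 gap is not stated in the
# deposition, so both cross-chain pairings are listed per model; expected values
# are Calpha-Calpha distances in angstroms.
label	model	chain_a	res_a	chain_b	res_b	atom	expected
NBD gap site 1 (Ser50-Ser148)	bound	A	50	B	148	CA	8.1
NBD gap site 2 (Ser148-Ser50)	bound	B	50	A	148	CA	8.1
NBD gap site 1 (Ser50-Ser148)	apo	A	50	B	148	CA	17.2
NBD gap site 2 (Ser148-Ser50)	apo	B	50	A	148	CA	23.6
Pocket gate Leu403-Leu754	bound	C	403	C	754	CA	6.6
Pocket gate Leu403-Leu754	apo	C	403	C	754	CA	19.2
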