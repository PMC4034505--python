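accession	description_ranking	description_selection
JACR890101	Normalized hydrophobicity scales for alpha/beta-proteins (Cid et al., 1992)	Number of full nonbonding orbitals (Fauchere et al., 1988)
COWR900101	Consensus normalized hydrophobicity scale (Eisenberg, 1984)	Conformational preference for parallel beta-strands (Lifson-Sander, 1979)
ZIMJ680103	Polarity (Grantham, 1974)	Retention coefficient in NaH2PO4 (Meek-Rossetti, 1981)
MEEJ810102	Hydration number (Hopfinger, 1971), Cited by Charton-Charton (1982)	Average number of surrounding residues (Ponnuswamy et al., 1980)
FAUJ880110	Conformational preference for parallel beta-strands (Lifson-Sander, 1979)	Polarity (Zimmerman et al., 1968)
WARP780101	Retention coefficient in NaClO4 (Meek-Rossetti, 1981)	Average interactions per side chain atom (Warme-Morgan, 1978)
PONP800108	Average number of surrounding residues (Ponnuswamy et al., 1980)	Weights from the IFH scale (Jacobs-White, 1989)
LIFS790102	Transfer-free energy from chx to oct (Radzicka-Wolfenden, 1988)	Hydrophobicity index, 3.0 pH (Cowan-Whittaker, 1990)
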