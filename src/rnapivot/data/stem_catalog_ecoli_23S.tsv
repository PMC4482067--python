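# Best-effort stem catalog for E. coli 23S rRNA pivot helices, keyed to standard
# E. coli numbering (chain id 'A' as in isolated-subunit deposits; adjust
# to the chain naming of the files being compared).  Stem ranges are
# placeholder 5'-side octamers proximal to each catalog pivot site and
# should be refined against secondary-structure diagrams before
# quantitative use; tip residues default to the last path residue.
helix_id	chain	stem_ranges	path_ranges	tip_residue
H34	A	694-701	702-717	NA
H38	A	861-868	869-884	NA
H42	A	1023-1030	1031-1046	NA
H69	A	1898-1905	1906-1921	NA
H76	A	2090-2097	2098-2113	NA
H84	A	2289-2296	2297-2312	NA
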