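# Best-effort stem catalog for E. coli 16S rRNA pivot helices, keyed to standard
# E. coli numbering (chain id 'A' as in isolated-subunit deposits; adjust
# to the chain naming of the files being compared).  Stem ranges are
# placeholder 5'-side octamers proximal to each catalog pivot site and
# should be refined against secondary-structure diagrams before
# quantitative use; tip residues default to the last path residue.
helix_id	chain	stem_ranges	path_ranges	tip_residue
h6	A	53-60	61-76	NA
h8	A	136-143	144-159	NA
h21	A	580-587	588-603	NA
h26	A	823-830	831-846	NA
h28	A	1385-1392	1393-1408	NA
h31	A	946-953	954-969	NA
h32	A	1203-1210	1211-1226	NA
h33	A	1033-1040	1041-1056	NA
h36	A	1065-1072	1073-1088	NA
h37	A	1067-1074	1075-1090	NA
h39	A	1116-1123	1124-1139	NA
h40	A	1147-1154	1155-1170	NA
h41	A	1233-1240	1241-1256	NA
h42	A	1295-1302	1303-1318	NA
h43	A	1342-1349	1350-1365	NA
h44	A	1393-1400	1401-1416	NA
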