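gene	species	clade	window
CAMK1	human	other_mammals	gtcttgggggtttag
CAMK1	opossum	marsupials	1
CAMK1	chicken	birds	0
CAMK1	anole_lizard	reptiles	0
CAMK1	zebrafish	fish	0
CNOT3	human	other_mammals	gttctgtgggggcag
CNOT3	opossum	marsupials	1
CNOT3	chicken	birds	0
CNOT3	anole_lizard	reptiles	0
CNOT3	zebrafish	fish	0
DUSP12	human	other_mammals	gtttgggggttgcag
DUSP12	opossum	marsupials	1
DUSP12	chicken	birds	0
DUSP12	anole_lizard	reptiles	0
DUSP12	zebrafish	fish	0
FES	human	other_mammals	ccgtctcgggggcag
FES	opossum	marsupials	1
FES	chicken	birds	0
FES	anole_lizard	reptiles	0
FES	zebrafish	fish	0
TRPV1	human	other_mammals	gctccccgggggcag
TRPV1	opossum	marsupials	0
TRPV1	chicken	birds	0
TRPV1	anole_lizard	reptiles	0
TRPV1	zebrafish	fish	0
SLC44A2	human	other_mammals	ccggggggagcccag
SLC44A2	opossum	marsupials	1
SLC44A2	chicken	birds	0
SLC44A2	anole_lizard	reptiles	0
SLC44A2	zebrafish	fish	0
RQCD1	human	other_mammals	ttttgggggaaacag
RQCD1	opossum	marsupials	1
RQCD1	chicken	birds	0
RQCD1	anole_lizard	reptiles	0
RQCD1	zebrafish	fish	0
PFN2	human	other_mammals	tttggtggggggcag
PFN2	opossum	marsupials	0
PFN2	chicken	birds	0
PFN2	anole_lizard	reptiles	0
PFN2	zebrafish	fish	0
PDZK1	human	other_mammals	gttgggggagggtag
PDZK1	opossum	marsupials	1
PDZK1	chicken	birds	0
PDZK1	anole_lizard	reptiles	0
PDZK1	zebrafish	fish	0
LRRC23	human	other_mammals	gccctgggggtctag
LRRC23	opossum	marsupials	0
LRRC23	chicken	birds	0
LRRC23	anole_lizard	reptiles	0
LRRC23	zebrafish	fish	0
LAMB1	human	other_mammals	tttatcgggtgacag
LAMB1	opossum	marsupials	0
LAMB1	chicken	birds	0
LAMB1	anole_lizard	reptiles	0
LAMB1	zebrafish	fish	0
C3orf62	human	other_mammals	acctgggggctgcag
C3orf62	opossum	marsupials	1
C3orf62	chicken	birds	0
C3orf62	anole_lizard	reptiles	0
C3orf62	zebrafish	fish	0
PRMT5	human	other_mammals	ggtgggggagtgcag
PRMT5	opossum	marsupials	1
PRMT5	chicken	birds	0
PRMT5	anole_lizard	reptiles	0
PRMT5	zebrafish	fish	0
PAOX	human	other_mammals	tgtttgcgggggaag
PAOX	opossum	marsupials	1
PAOX	chicken	birds	1
PAOX	anole_lizard	reptiles	1
PAOX	zebrafish	fish	1
METTL13	human	other_mammals	cctgggcgggggcag
METTL13	opossum	marsupials	1
METTL13	chicken	birds	1
METTL13	anole_lizard	reptiles	1
METTL13	zebrafish	fish	1
MICA	human	other_mammals	gctgggtgggggcag
MICA	opossum	marsupials	1
MICA	chicken	birds	0
MICA	anole_lizard	reptiles	ND
MICA	zebrafish	fish	ND
FAM113	human	other_mammals	ggggggggtgggtag
FAM113	opossum	marsupials	1
FAM113	chicken	birds	ND
FAM113	anole_lizard	reptiles	0
FAM113	zebrafish	fish	0
PAX8	human	other_mammals	cccggggggtaccag
PAX8	opossum	marsupials	1
PAX8	chicken	birds	ND
PAX8	anole_lizard	reptiles	0
PAX8	zebrafish	fish	0
ABCC11	human	other_mammals	ttctgggaaacgaag
ABCC11	opossum	marsupials	0
ABCC11	chicken	birds	ND
ABCC11	anole_lizard	reptiles	0
ABCC11	zebrafish	fish	0
HLA-G	human	other_mammals	aaggggtggggccag
HLA-G	opossum	marsupials	1
HLA-G	chicken	birds	ND
HLA-G	anole_lizard	reptiles	ND
HLA-G	zebrafish	fish	ND
HLA-H	human	other_mammals	cgggggcggggccag
HLA-H	opossum	marsupials	1
HLA-H	chicken	birds	ND
HLA-H	anole_lizard	reptiles	ND
HLA-H	zebrafish	fish	ND
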