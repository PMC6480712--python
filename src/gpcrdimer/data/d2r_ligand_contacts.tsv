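# Close-contact fingerprints (<3.5 A) of three antipsychotics in the D2
# dopamine receptor orthosteric pocket: co-crystallized risperidone and the
# MD-stable poses of clozapine and spiperone, as reported with their
# common/unique category tags: (I) all three ligands, (II) risperidone and
# clozapine, (III) risperidone and spiperone, (IV) clozapine and spiperone,
# "unique" otherwise. Labels are Ballesteros-Weinstein positions or loop
# segments, carried as annotations only.
# ligand	res_name	res_seq	label	category
risperidone	TRP	100	ECL1	unique
risperidone	SER	197	5.48	unique
risperidone	PHE	382	6.44	unique
risperidone	TYR	416	7.43	unique
risperidone	ASP	114	3.32	I
risperidone	CYS	118	3.36	III
risperidone	ILE	122	3.40	III
risperidone	TRP	386	6.48	II
risperidone	PHE	389	6.51	II
clozapine	PHE	189	5.38	unique
clozapine	PHE	198	5.47	unique
clozapine	PHE	390	6.52	unique
clozapine	HIS	393	6.55	unique
clozapine	ASP	114	3.32	I
clozapine	VAL	115	3.33	IV
clozapine	ILE	184	ECL2	IV
clozapine	SER	193	5.42	IV
clozapine	TRP	386	6.48	II
clozapine	PHE	389	6.51	II
spiperone	VAL	91	2.61	unique
spiperone	PHE	110	3.28	unique
spiperone	ASP	114	3.32	I
spiperone	VAL	115	3.33	IV
spiperone	CYS	118	3.36	III
spiperone	ILE	122	3.40	III
spiperone	ILE	184	ECL2	IV
spiperone	SER	193	5.42	IV
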