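protein_id	mutation	second_base	location	structure	exposure	conservation_grade	predicted_effect	clinical_significance
EAA1	I59T	U->C	TM1	a-helix	Exposed	3	benign	-
EAA1	I63T	U->C	TM1	a-helix	Exposed	2	benign	uncertain
EAA1	I133T	U->C	TM3	a-helix	Exposed	4	? damaging	-
EAA1	I214T	U->C	ECL2	loop	-	1	benign	uncertain(EA6)
EAA1	I310T	U->C	ECL3	loop	Exposed	5	benign	-
EAA1	I349T	U->C	IM	a-helix	Buried	5	damaging	uncertain
EAA1	I397T	U->C	TM7	a-helix	Exposed(F)	8	damaging	-
EAA1	I526T	U->C	Intracellular	C-coil	-	5	? damaging	-
EAA2	I325T	U->C	TM6	a-helix	Exposed	2	benign	-
EAA2	I504T	U->C	Intracellular	a-helix	-	1	benign	-
EAA2	I514T	U->C	Intracellular	a-helix	-	3	benign	uncertain
EAA2	I522T	U->C	Intracellular	a-helix	-	2	benign	-
EAA3	I72T	U->C	TM2	a-helix	Exposed	7	benign	-
EAA3	I90T	U->C	ICL1	a-helix	Buried	8	damaging	uncertain
EAA3	I104T	U->C	TM3	a-helix	Exposed	4	benign	uncertain(DCBXA)
EAA3	I127T	U->C	ECL2	loop	Buried	1	? damaging	-
EAA3	I271T	U->C	ECL3	a-helix	Buried	6	benign	uncertain(DCBXA)
EAA3	I298T	U->C	TM6	a-helix	Exposed	4	benign	uncertain(DCBXA)
EAA3	I304T	U->C	TM6	a-helix	Exposed	7	? damaging	-
EAA3	I307T	U->C	TM6	a-helix	Exposed	3	benign	uncertain(DCBXA)
EAA3	I391T	U->C	ECL4	a-helix	Exposed	4	benign	-
EAA3	I397T	U->C	IM	a-helix	Buried	8	? damaging	-
EAA3	I481T	U->C	Intracellular	a-helix	-	4	benign	-
EAA3	L92Q	U->A	ICL1	a-helix	Exposed	3	damaging	-
EAA3	L443Q	U->A	TM8	a-helix	Buried	8	damaging	-
EAA3	F50Y	U->A	ECL1	a-helix	Exposed	5	benign	benign(DCBXA)
EAA3	F508Y	U->A	Intracellular	C-coil	-	7	damaging	-
EAA4	I141T	U->C	TM3	a-helix	Exposed	5	benign	-
EAA4	I152T	U->C	TM3	a-helix	Exposed	4	benign	-
EAA4	I282T	U->C	TM4	a-helix	Buried	8	benign	-
EAA4	I374T	U->C	IM	a-helix	Exposed	4	benign	-
EAA4	F351Y	U->A	TM6	a-helix	Exposed	3	benign	-
VGLUT1	I128T	U->C	TM2	a-helix	-	6	benign	-
VGLUT2	I8T	U->C	Intracellular	loop	-	-	benign	-
VGLUT2	I41T	U->C	Intracellular	b-strand	-	6	benign	-
VGLUT2	I73T	U->C	TM1	a-helix	-	6	? damaging	-
VGLUT2	I286T	U->C	ICL2	a-helix	Exposed	5	? damaging	-
VGLUT2	I365T	U->C	TM8	a-helix	Exposed	3	benign	-
VGLUT2	I369T	U->C	TM8	a-helix	Exposed	4	benign	-
VGLUT2	I482T	U->C	TM12	a-helix	Exposed(F)	8	? damaging	-
VGLUT3	I13T	U->C	Intracellular	a-helix	-	6	benign	-
VGLUT3	I100T	U->C	ECL1	a-helix	-	8	damaging	-
VGLUT3	I141T	U->C	TM2	3/10-helix	-	6	damaging	-
VGLUT3	I291T	U->C	ICL3	a-helix	Exposed	6	damaging	-
VGLUT3	I320T	U->C	TM7	a-helix	Buried	6	damaging	uncertain
VGLUT3	I369T	U->C	TM8	a-helix	Exposed	3	? damaging	uncertain(DFNA25)
VGLUT3	I467T	U->C	TM11	a-helix	Exposed	6	damaging	-
VGLUT3	I523T	U->C	Intracellular	loop	-	4	damaging	-
YLAT2	I82T	U->C	TM2	a-helix	Exposed	5	benign	-
YLAT2	I115T	U->C	TM3	a-helix	Buried	8	damaging	-
YLAT2	I174T	U->C	TM4	a-helix	Buried	7	? damaging	-
YLAT2	I204T	U->C	TM5	a-helix	Exposed	2	benign	-
YLAT2	I283T	U->C	TM7	a-helix	Exposed	5	benign	-
YLAT2	I336T	U->C	ICL4	a-helix	Buried	6	? damaging	-
YLAT2	I359T	U->C	ICL4	b-strand	Exposed(F)	8	? damaging	-
YLAT2	I361T	U->C	ICL4	loop	Exposed	4	benign	-
YLAT2	I434T	U->C	TM11	a-helix	Exposed	4	benign	-
YLAT2	I441T	U->C	TM11	a-helix	Exposed	5	benign	-
YLAT2	I453T	U->C	TM12	a-helix	Exposed	6	damaging	-
YLAT2	I457T	U->C	TM12	a-helix	Exposed	7	damaging	benign
YLAT2	I487T	U->C	Intracellular	a-helix	-	1	benign	-
YLAT2	F343Y	U->A	ICL4	a-helix	Buried	5	? damaging	-
YLAT2	F387Y	U->A	TM10	a-helix	Exposed	4	? damaging	-
EAA1	T2I	C->U	Intracellular	N-coil	-	-	benign	-
EAA1	T67I	C->U	TM1	a-helix	Exposed	3	benign	-
EAA1	T225I	C->U	ECL2	b-strand	-	1	benign	-
EAA1	T428I	C->U	IM	a-helix	Exposed	7	damaging	-
EAA2	T433I	C->U	IM	a-helix	Buried(F)	9	damaging	-
EAA2	Q152L	A->U	ECL2	a-helix	-	3	benign	-
EAA3	T133I	C->U	ECL2	loop	Exposed	3	? damaging	-
EAA3	T164I	C->U	ECL2	b-strand	Buried(S)	9	? damaging	-
EAA3	T197I	C->U	ECL2	loop	-	4	? damaging	-
EAA3	T340I	C->U	IM	a-helix	Buried(S)	9	damaging	-
EAA3	T364I	C->U	TM7	a-helix	Buried(S)	9	? damaging	-
EAA3	T370I	C->U	TM7	a-helix	Buried(S)	9	damaging	-
EAA3	Y285F	A->U	ECL3	a-helix	Buried	8	benign	-
EAA4	T343I	C->U	ECL3	a-helix	Buried	6	benign	-
EAA4	T366I	C->U	ICL3	a-helix	Buried	8	benign	-
EAA4	T412I	C->U	TM7	a-helix	Buried	8	damaging	-
EAA4	T507I	C->U	TM8	a-helix	Buried	5	damaging	-
EAA4	Q27L	A->U	Intracellular	a-helix	-	5	benign	-
EAA4	Q549L	A->U	Intracellular	a-helix	-	6	? damaging	-
VGLUT1	T96I	C->U	ECL1	b-strand	-	3	benign	-
VGLUT1	T209I	C->U	TM5	a-helix	Exposed	4	benign	-
VGLUT1	T464I	C->U	ECL5	loop	Exposed	7	benign	-
VGLUT2	T164I	C->U	TM3	a-helix	-	4	benign	-
VGLUT2	T217I	C->U	TM5	a-helix	Exposed	5	benign	-
VGLUT3	T40I	C->U	Intracellular	loop	-	4	benign	-
VGLUT3	T119I	C->U	ECL1	loop	-	1	benign	uncertain
VGLUT3	T305I	C->U	ICL3	loop	Buried	7	damaging	-
VGLUT3	T384I	C->U	ICL4	loop	Exposed	7	damaging	-
VGLUT3	T551I	C->U	Intracellular	loop	-	5	damaging	-
YLAT2	T10I	C->U	Intracellular	N-coil	-	-	benign	-
YLAT2	T74I	C->U	ECL1	a-helix	Buried	6	? damaging	-
YLAT2	Q40L	A->U	Intracellular	N-coil	Exposed	1	benign	-
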