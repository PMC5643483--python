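name	formula	function	pathway_class	strains	fragmentation_confirmed	detected_dshibae	detected_pinhibens	other_studies	mesocosm	north_sea
HET (4-methyl-5-(β-hydroxyethyl)thiazole)	C6H9NOS	vitamin B1 precursor	biosynthetic	dshibae;pinhibens	0	1	1		0	0
Thiamine phosphate	C10H15N2O8P	vitamin B1	biosynthetic	dshibae;pinhibens	0	1	1	G, J	0	0
Dimethyl-D-ribityl-lumazine	C13H18N4O6	vitamin B2 precursor	biosynthetic	dshibae;pinhibens	1	1	1	R	0	0
Riboflavin	C17H20N4O6	vitamin B2	biosynthetic	dshibae;pinhibens	1	1	1	F, R, G, J	0	0
Pantoate	C6H12O4	vitamin B5 precursor	biosynthetic	dshibae;pinhibens	0	1	0		0	0
Pantothenate	C9H17NO5	vitamin B5	biosynthetic	dshibae;pinhibens	0	1	1	G, J	0	0
Pyridoxal	C8H9NO3	vitamin B6 related	biosynthetic	dshibae;pinhibens	0	1	1		1	1
Pyridoxal phosphate	C8H10NO6P	vitamin B6	biosynthetic	dshibae;pinhibens	0	1	1		0	0
Dethiobiotin	C10H17N2O3	vitamin B7 precursor	biosynthetic	dshibae;pinhibens	0	0	1		0	0
Alpha-ribazole	C14H18N2O4	vitamin B12 precursor	biosynthetic	dshibae;pinhibens	1	1	1	R, J	1	1
Alpha-ribazole-5-phosphate	C14H19N2O7P	vitamin B12 precursor	biosynthetic	dshibae;pinhibens	0	1	1		0	1
Pyrroloquinoline quinone	C14H6N2O8	vit. B - cofactor	biosynthetic	dshibae;pinhibens	1	1	0		0	0
6-(2-amino-2-carboxylatoethyl)-1,2,3,4-tetrahydroquinoline-2,4-dicarboxylate	C14H14N2O6	vit. B - cofactor	biosynthetic	dshibae;pinhibens	0	1	0		1	1
Methyl (indole-3-yl)acetate	C11H11NO2	IAA related	biosynthetic	dshibae;pinhibens	0	1	1		1	0
Tryptophan	C11H12N2O2	IAA precursor	biosynthetic	dshibae;pinhibens	0	1	1	F, R, G	1	0
Indole_acetate	C10H9NO2	IAA	biosynthetic	dshibae;pinhibens	0	1	0	F	0	0
2,3-dihydroxybenzoate	C7H5O4	siderophore building block	biosynthetic	dshibae;pinhibens	0	1	0	F	0	0
3-4-dihydroxybenzoate	C7H6O4	siderophore building block	biosynthetic	dshibae;pinhibens	0	0	1		0	0
PAI-1 (N-(3-oxododecanoyl)-L-homoserine lactone)	C16H27NO4	quorum-sensing	biosynthetic	dshibae;pinhibens	1	1	1		0	0
AAI	C12H19NO4	quorum-sensing	biosynthetic	dshibae;pinhibens	0	1	1		1	0
VAI-2	C12H21NO3	quorum-sensing	biosynthetic	dshibae;pinhibens	0	1	1		0	0
VAI-1	C10H15NO4	quorum-sensing	biosynthetic	dshibae;pinhibens	0	1	1		1	1
HAI-1	C8H13NO4	quorum-sensing	biosynthetic	dshibae;pinhibens	0	1	1		1	0
N-3-hydroxydecanoyl-L-homoserine lactone	C14H25NO4	quorum-sensing	biosynthetic	dshibae;pinhibens	1	0	1	J	0	0
Porphobilinogen	C10H14N2O4	AA derivate	biosynthetic	dshibae;pinhibens	0	1	1		1	1
Tyrosine	C9H11NO3	AA	biosynthetic	dshibae;pinhibens	0	1	1	R, G	1	1
Arogenate	C10H13NO5	AA precursor	biosynthetic	dshibae;pinhibens	0	1	1	R	1	1
4-Hydroxy-phenylpyruvate	C9H8O4	AA precursor	biosynthetic	dshibae;pinhibens	0	1	1		1	1
Phenylalanine	C9H11NO2	AA	biosynthetic	dshibae;pinhibens	0	1	0	F, R, G	1	1
L-SDAP	C11H18N2O7	AA precursor	biosynthetic	dshibae;pinhibens	0	1	1		0	0
2-Isopropylmaleate	C7H10O4	AA precursor	biosynthetic	dshibae;pinhibens	0	1	1	R	1	0
Delta-piperideine-2-6-dicarboxylate	C7H9NO4	AA precursor	biosynthetic	dshibae;pinhibens	0	1	1		1	1
O-Acetyl-L-homoserine	C6H11NO4	AA derivate	biosynthetic	dshibae;pinhibens	0	1	1		1	0
Histidine	C6H9N3O2	AA	biosynthetic	dshibae;pinhibens	0	1	1	G, J	0	0
Miraxanthin V	C17H18N2O6	betaxanthine	biosynthetic	dshibae;pinhibens	0	0	1		1	1
L-Dihydroxy-phenylalanine	C9H11NO4	betaxanthine	biosynthetic	dshibae;pinhibens	0	0	1		1	1
Glutathione	C10H17N3O6S	defense	biosynthetic	dshibae;pinhibens	0	1	1	R	0	0
Tropodithietic acid	C8H4O3S2	antibiotic	biosynthetic	dshibae;pinhibens	1	0	1		0	0
Inosine	C10H12N4O5	purin metabolism	biosynthetic	dshibae;pinhibens	0	1	1	F, R	0	0
Thymidine	C10H14N2O5		biosynthetic	dshibae;pinhibens	0	1	0	R	1	1
Deoxycytidine	C9H13N3O4		biosynthetic	dshibae;pinhibens	0	1	1		0	0
Phenylacetylcarbinol	C9H10O2		biosynthetic	dshibae;pinhibens	0	0	1		0	1
S-Methyl phenylethanethioate	C9H10OS		biosynthetic	dshibae;pinhibens	0	0	1	T	0	0
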