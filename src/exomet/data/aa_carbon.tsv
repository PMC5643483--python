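amino_acid	carbon_atoms
alanine	3
arginine	6
asparagine	4
aspartate	4
cysteine	3
glutamate	5
glutamine	5
glycine	2
histidine	6
isoleucine	6
leucine	6
lysine	6
methionine	5
phenylalanine	9
proline	5
serine	3
threonine	4
tryptophan	11
tyrosine	9
valine	5
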