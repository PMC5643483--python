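function_label	group
vitamin B1 precursor	vitamin-related
vitamin B1	vitamin-related
vitamin B2 precursor	vitamin-related
vitamin B2	vitamin-related
vitamin B5 precursor	vitamin-related
vitamin B5	vitamin-related
vitamin B6 related	vitamin-related
vitamin B6	vitamin-related
vitamin B7 precursor	vitamin-related
vitamin B12 precursor	vitamin-related
vit. B - cofactor	vitamin-related
quorum-sensing	quorum-sensing
AA	amino-acid-related
AA precursor	amino-acid-related
AA derivate	amino-acid-related
IAA	auxin-related
IAA precursor	auxin-related
IAA related	auxin-related
siderophore building block	siderophore
defense	defense/antibiotic
antibiotic	defense/antibiotic
purin metabolism	nucleoside
betaxanthine	other
unspecified	other
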