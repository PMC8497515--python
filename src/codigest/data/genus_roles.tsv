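genus	roles	note
Escherichia	growth_metabolism,acidogenesis_acetogenesis	facultative anaerobe, broad carbon-source range, acidogenic
Glutamicibacter	growth_metabolism,lignocellulose	lignocellulose saccharification, amino acid metabolism
Psychrobacter	growth_metabolism	cold-active enzymes supporting ATP/ADP generation at low temperature
Aerococcus	growth_metabolism,acidogenesis_acetogenesis,pathogenic	acid production from carbohydrates; some species pathogenic
Oceanisphaera	growth_metabolism	selenocompound, arachidonic and 2-oxocarboxylic acid metabolism
Turicibacter	growth_metabolism	fat, carbohydrate, amino acid and nucleic acid metabolism
Romboutsia	growth_metabolism	broad carbohydrate use, amino acid fermentation, vitamin synthesis
Jeotgalicoccus	lignocellulose,acidogenesis_acetogenesis	terminal alkene production, fatty acid decarboxylation
Enterococcus	acidogenesis_acetogenesis	fermentation of carbohydrates to lactic acid
Staphylococcus	acidogenesis_acetogenesis	lactate and acetate accumulation under hypoxia
Lactobacillus	acidogenesis_acetogenesis	hexose fermentation to lactate, CO2, acetate or ethanol
Corynebacterium	acidogenesis_acetogenesis	fermentative carbohydrate metabolism to lactic acid
Prevotella	acidogenesis_acetogenesis	glucose to acetate, formate and succinate
Terrisporobacter	acidogenesis_acetogenesis	glucose fermentation to acetate
Streptococcus	acidogenesis_acetogenesis,pathogenic	acid-generating carbohydrate metabolism; mostly pathogenic
Clostridium	acidogenesis_acetogenesis,pathogenic	carbohydrates to succinate and acetate; most species pathogenic
Sporobacter	acidogenesis_acetogenesis	organic compound metabolism yielding acetate
Asaccharospora	pathogenic	A. irregularis resembles pathogenic clostridia
Acinetobacter	pathogenic,growth_metabolism	mostly pathogenic; amino acid, carbohydrate and lipid metabolism
Pseudomonas	pathogenic,growth_metabolism	anaerobic energy metabolism, carbon catabolite repression; virulence factors
Treponema	pathogenic	pathogenic spirochaetes
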