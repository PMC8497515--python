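pathway	tag
fructose and mannose metabolism	hydrolysis
starch and sucrose metabolism	acidogenesis_acetogenesis
amino acid and nucleotide sugar metabolism	hydrolysis
phosphotransferase system (pts)	hydrolysis
phosphotransferase system	hydrolysis
glyoxylate and dicarboxylate metabolism	acidogenesis_acetogenesis
pyruvate metabolism	acidogenesis_acetogenesis
butanoate metabolism	acidogenesis_acetogenesis
propanoate metabolism	acidogenesis_acetogenesis
riboflavin metabolism	growth_support
selenocompound metabolism	growth_support
phenylalanine metabolism	growth_support
tyrosine metabolism	growth_support
glycine, serine and threonine metabolism	growth_support
d-alanine metabolism	growth_support
linoleic acid metabolism	growth_support
tryptophan metabolism	growth_support
aminobenzoate degradation	hydrolysis
naphthalene degradation	hydrolysis
ethylbenzene degradation	hydrolysis
polycyclic aromatic hydrocarbon degradation	hydrolysis
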