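Escherichia
Lactobacillus
Bacteroides
Clostridium
Streptococcus
Staphylococcus
Pseudomonas
Bacillus
Helicobacter
Prevotella
Dialister
Gardnerella
Alkanindiges
Granulicatella
Turicibacter
Fusibacter
Alkaliphilus
Veillonella
Porphyromonas
Bifidobacterium
Akkermansia
Faecalibacterium
Roseburia
Ruminococcus
Enterococcus
Klebsiella
Salmonella
Shigella
Campylobacter
Haemophilus
Neisseria
Moraxella
Corynebacterium
Propionibacterium
Actinomyces
Fusobacterium
Leptotrichia
Treponema
Borrelia
Chlamydia
Mycobacterium
Mycoplasma
Legionella
Listeria
Vibrio
Yersinia
Proteus
Serratia
Citrobacter
Enterobacter
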