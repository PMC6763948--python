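end-stage renal disease	gut	ESRD
kidney stones	gut
diarrhea	gut
liver cirrhosis	gut
malnutrition	gut
ileal Crohn disease	gut
necrotizing enterocolitis	gut
colon cancer	gut
infectious colitis	gut
constipation	gut
colitis	gut
ulcerative colitis	gut
Whipple disease	gut
irritable bowel syndrome	gut	IBS
gastroesophageal reflux	gut
Crohn disease	gut	CD
gastric and duodenal ulcer	gut
inflammatory bowel disease	gut	IBD
Clostridium difficile infection	gut	CDI
colorectal carcinoma	gut	colorectal cancer
skin and mucosal infections	skin
atopic dermatitis	skin
psoriasis	skin
guttate psoriasis	skin
atopic sensitization	skin
eczema	skin
atopy	skin
asthma	lungs
allergic asthma	lungs
recurrent wheeze	lungs
chronic obstructive pulmonary disease	lungs
cystic fibrosis	lungs
multiple sclerosis	brain
Parkinson's disease	brain
schizophrenia	brain
autism	brain
depression	brain
urinary tract infection	urogenital
bacterial vaginosis	urogenital
polycystic ovary syndrome	urogenital
preterm birth	urogenital
type 1 diabetes	systemic
diabetes	systemic
type 2 diabetes	systemic
HIV/AIDS	systemic	HIV|AIDS
obesity	systemic
systemic inflammatory response syndrome	systemic
allergic sensitization	systemic
allergy	systemic
ulcer	systemic
periodontitis	systemic
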