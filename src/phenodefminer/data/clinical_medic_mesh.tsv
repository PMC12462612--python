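term	term_id
inflammation	MESH:00001
fibrosis	MESH:00002
ischemia	MESH:00003
necrosis	MESH:00004
hypoxia	MESH:00005
thrombosis	MESH:00006
embolism	MESH:00007
stenosis	MESH:00008
aneurysm	MESH:00009
neuropathy	MESH:00010
retinopathy	MESH:00011
nephropathy	MESH:00012
cardiomyopathy	MESH:00013
hepatomegaly	MESH:00014
splenomegaly	MESH:00015
lymphadenopathy	MESH:00016
osteopenia	MESH:00017
hypercalcemia	MESH:00018
hyponatremia	MESH:00019
hyperkalemia	MESH:00020
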