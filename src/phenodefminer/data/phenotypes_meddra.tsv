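term	term_id
asthma	MDR:00001
hypertension	MDR:00002
type 2 diabetes mellitus	MDR:00003
myocardial infarction	MDR:00004
atrial fibrillation	MDR:00005
heart failure	MDR:00006
stroke	MDR:00007
coma	MDR:00008
depression	MDR:00009
epilepsy	MDR:00010
chronic kidney disease	MDR:00011
rheumatoid arthritis	MDR:00012
psoriasis	MDR:00013
osteoporosis	MDR:00014
obesity	MDR:00015
anaphylaxis	MDR:00016
pneumonia	MDR:00017
sepsis	MDR:00018
migraine	MDR:00019
glaucoma	MDR:00020
anemia	MDR:00021
hypothyroidism	MDR:00022
hyperlipidemia	MDR:00023
pancreatitis	MDR:00024
cirrhosis	MDR:00025
schizophrenia	MDR:00026
dementia	MDR:00027
pulmonary embolism	MDR:00028
deep vein thrombosis	MDR:00029
breast cancer	MDR:00030
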