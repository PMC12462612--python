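term	term_id
asthma	SCT:00001
hypertension	SCT:00002
type 2 diabetes mellitus	SCT:00003
chronic obstructive pulmonary disease	SCT:00004
ischemic heart disease	SCT:00005
parkinson disease	SCT:00006
multiple sclerosis	SCT:00007
ulcerative colitis	SCT:00008
crohn disease	SCT:00009
celiac disease	SCT:00010
gout	SCT:00011
sleep apnea	SCT:00012
endometriosis	SCT:00013
melanoma	SCT:00014
prostate cancer	SCT:00015
colorectal cancer	SCT:00016
osteoarthritis	SCT:00017
cystic fibrosis	SCT:00018
sickle cell disease	SCT:00019
hepatitis c	SCT:00020
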