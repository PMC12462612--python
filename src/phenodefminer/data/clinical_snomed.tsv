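term	term_id
chest pain	SCT:00001
dyspnea	SCT:00002
fever	SCT:00003
cough	SCT:00004
fatigue	SCT:00005
headache	SCT:00006
nausea	SCT:00007
vomiting	SCT:00008
dizziness	SCT:00009
syncope	SCT:00010
edema	SCT:00011
tachycardia	SCT:00012
bradycardia	SCT:00013
hyperglycemia	SCT:00014
hypoglycemia	SCT:00015
proteinuria	SCT:00016
hematuria	SCT:00017
jaundice	SCT:00018
ascites	SCT:00019
wheezing	SCT:00020
rash	SCT:00021
pruritus	SCT:00022
seizure	SCT:00023
tremor	SCT:00024
palpitations	SCT:00025
weight loss	SCT:00026
weight gain	SCT:00027
night sweats	SCT:00028
insomnia	SCT:00029
anxiety	SCT:00030
delirium	SCT:00031
confusion	SCT:00032
dysphagia	SCT:00033
diarrhea	SCT:00034
constipation	SCT:00035
back pain	SCT:00036
joint pain	SCT:00037
muscle weakness	SCT:00038
visual impairment	SCT:00039
hearing loss	SCT:00040
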