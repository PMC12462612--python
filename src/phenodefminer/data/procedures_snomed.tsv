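term	term_id
appendectomy	SCT:00001
cholecystectomy	SCT:00002
colonoscopy	SCT:00003
coronary angiography	SCT:00004
coronary artery bypass grafting	SCT:00005
echocardiography	SCT:00006
electrocardiography	SCT:00007
endoscopy	SCT:00008
hemodialysis	SCT:00009
hip replacement	SCT:00010
knee arthroplasty	SCT:00011
laparoscopy	SCT:00012
lumbar puncture	SCT:00013
mammography	SCT:00014
mastectomy	SCT:00015
mechanical ventilation	SCT:00016
pacemaker implantation	SCT:00017
splenectomy	SCT:00018
thyroidectomy	SCT:00019
tonsillectomy	SCT:00020
tracheostomy	SCT:00021
transfusion	SCT:00022
cesarean section	SCT:00023
cardiac catheterization	SCT:00024
biopsy	SCT:00025
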