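term	term_id
metformin	DB:00001
insulin	DB:00002
aspirin	DB:00003
warfarin	DB:00004
atorvastatin	DB:00005
simvastatin	DB:00006
lisinopril	DB:00007
amlodipine	DB:00008
metoprolol	DB:00009
losartan	DB:00010
hydrochlorothiazide	DB:00011
furosemide	DB:00012
albuterol	DB:00013
fluticasone	DB:00014
montelukast	DB:00015
prednisone	DB:00016
ibuprofen	DB:00017
acetaminophen	DB:00018
omeprazole	DB:00019
levothyroxine	DB:00020
sertraline	DB:00021
fluoxetine	DB:00022
gabapentin	DB:00023
amoxicillin	DB:00024
azithromycin	DB:00025
ciprofloxacin	DB:00026
clopidogrel	DB:00027
digoxin	DB:00028
spironolactone	DB:00029
salbutamol	DB:00030
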