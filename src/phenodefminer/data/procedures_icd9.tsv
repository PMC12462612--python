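term	term_id
spinal fusion	ICD9P:00001
hysterectomy	ICD9P:00002
prostatectomy	ICD9P:00003
nephrectomy	ICD9P:00004
craniotomy	ICD9P:00005
angioplasty	ICD9P:00006
amputation	ICD9P:00007
gastrectomy	ICD9P:00008
lobectomy	ICD9P:00009
valvuloplasty	ICD9P:00010
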