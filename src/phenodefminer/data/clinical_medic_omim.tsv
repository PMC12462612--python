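term	term_id
marfan syndrome	OMIM:00001
fragile x syndrome	OMIM:00002
huntington disease	OMIM:00003
duchenne muscular dystrophy	OMIM:00004
neurofibromatosis	OMIM:00005
phenylketonuria	OMIM:00006
wilson disease	OMIM:00007
gaucher disease	OMIM:00008
fabry disease	OMIM:00009
tay-sachs disease	OMIM:00010
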