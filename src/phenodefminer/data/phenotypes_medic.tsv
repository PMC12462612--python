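term	term_id
alzheimer disease	MESH:00001
amyotrophic lateral sclerosis	MESH:00002
autism spectrum disorder	MESH:00003
bipolar disorder	MESH:00004
cataract	MESH:00005
eczema	MESH:00006
fibromyalgia	MESH:00007
hemophilia	MESH:00008
lupus erythematosus	MESH:00009
lymphoma	MESH:00010
macular degeneration	MESH:00011
narcolepsy	MESH:00012
psoriatic arthritis	MESH:00013
scoliosis	MESH:00014
tuberculosis	MESH:00015
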