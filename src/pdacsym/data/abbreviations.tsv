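short	long
abd	abdominal
co	complains of
pt	patient
pts	patients
hx	history
fhx	family history
pmh	past medical history
nv	nausea vomiting
wt	weight
dx	diagnosis
cc	chief complaint
hpi	history of present illness
ros	review of systems
bilat	bilateral
rle	right lower extremity
lle	left lower extremity
rue	right upper extremity
lue	left upper extremity
yo	year old
sob	shortness of breath
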