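symptom_id	role	phrase
abdominal_epigastric_pain	trigger	abdominal pain
abdominal_epigastric_pain	trigger	epigastric pain
abdominal_epigastric_pain	trigger	stomach pain
abdominal_epigastric_pain	trigger	stomach ache
abdominal_epigastric_pain	trigger	stomachache
abdominal_epigastric_pain	trigger	belly pain
abdominal_epigastric_pain	trigger	belly ache
abdominal_epigastric_pain	trigger	bellyache
abdominal_epigastric_pain	trigger	tummy ache
abdominal_epigastric_pain	trigger	abdominal discomfort
abdominal_epigastric_pain	trigger	epigastric discomfort
abdominal_epigastric_pain	pain_location	abdomen
abdominal_epigastric_pain	pain_location	abdominal
abdominal_epigastric_pain	pain_location	epigastric
abdominal_epigastric_pain	pain_location	epigastrium
abdominal_epigastric_pain	pain_location	stomach
abdominal_epigastric_pain	pain_location	belly
abdominal_epigastric_pain	pain_location	tummy
abdominal_epigastric_pain	pain_term	pain
abdominal_epigastric_pain	pain_term	pains
abdominal_epigastric_pain	pain_term	ache
abdominal_epigastric_pain	pain_term	aches
abdominal_epigastric_pain	pain_term	aching
abdominal_epigastric_pain	pain_term	cramping
abdominal_epigastric_pain	pain_term	cramps
abdominal_epigastric_pain	pain_term	discomfort
abdominal_epigastric_pain	pain_term	tenderness
abdominal_epigastric_pain	pain_term	soreness
abdominal_epigastric_pain	pain_term	hurts
abdominal_epigastric_pain	pain_term	hurting
anorexia_early_satiety	trigger	anorexia
anorexia_early_satiety	trigger	anorexic
anorexia_early_satiety	trigger	early satiety
anorexia_early_satiety	trigger	poor appetite
anorexia_early_satiety	trigger	loss of appetite
anorexia_early_satiety	trigger	decreased appetite
anorexia_early_satiety	trigger	appetite loss
anorexia_early_satiety	trigger	no appetite
anorexia_early_satiety	trigger	early fullness
dark_urine	trigger	dark urine
dark_urine	trigger	dark colored urine
dark_urine	trigger	darker urine
dark_urine	trigger	tea colored urine
dark_urine	trigger	cola colored urine
dark_urine	trigger	brown urine
dark_urine	trigger	dark amber urine
epigastric_bloating	trigger	bloating
epigastric_bloating	trigger	bloated
epigastric_bloating	trigger	abdominal distension
epigastric_bloating	trigger	abdominal distention
epigastric_bloating	trigger	abdominal fullness
epigastric_bloating	trigger	epigastric fullness
nausea_vomiting	trigger	nausea
nausea_vomiting	trigger	nauseous
nausea_vomiting	trigger	nauseated
nausea_vomiting	trigger	vomiting
nausea_vomiting	trigger	vomited
nausea_vomiting	trigger	vomit
nausea_vomiting	trigger	emesis
nausea_vomiting	trigger	throwing up
nausea_vomiting	trigger	threw up
nausea_vomiting	trigger	queasy
nausea_vomiting	trigger	retching
pale_stool	trigger	pale stool
pale_stool	trigger	pale stools
pale_stool	trigger	clay colored stool
pale_stool	trigger	clay colored stools
pale_stool	trigger	claycolored stool
pale_stool	trigger	claycolored stools
pale_stool	trigger	light colored stool
pale_stool	trigger	light colored stools
pale_stool	trigger	acholic stool
pale_stool	trigger	acholic stools
pale_stool	trigger	gray stool
pale_stool	trigger	grey stool
back_pain	trigger	back pain
back_pain	trigger	backache
back_pain	trigger	back ache
back_pain	trigger	backpain
back_pain	pain_location	back
back_pain	pain_location	lumbar
back_pain	pain_location	flank
back_pain	pain_term	pain
back_pain	pain_term	pains
back_pain	pain_term	ache
back_pain	pain_term	aches
back_pain	pain_term	aching
back_pain	pain_term	cramping
back_pain	pain_term	cramps
back_pain	pain_term	discomfort
back_pain	pain_term	tenderness
back_pain	pain_term	soreness
back_pain	pain_term	hurts
back_pain	pain_term	hurting
fatigue	trigger	fatigue
fatigue	trigger	fatigued
fatigue	trigger	tired
fatigue	trigger	tiredness
fatigue	trigger	exhausted
fatigue	trigger	exhaustion
fatigue	trigger	lethargy
fatigue	trigger	lethargic
fatigue	trigger	low energy
fatigue	trigger	worn out
jaundice	trigger	jaundice
jaundice	trigger	jaundiced
jaundice	trigger	icterus
jaundice	trigger	icteric
jaundice	trigger	yellow skin
jaundice	trigger	yellowing of the skin
jaundice	trigger	yellow eyes
jaundice	trigger	yellowing of the eyes
jaundice	trigger	scleral icterus
jaundice	trigger	yellow sclera
malaise	trigger	malaise
malaise	trigger	feeling unwell
malaise	trigger	not feeling well
malaise	trigger	generally unwell
malaise	trigger	feeling poorly
pruritus	trigger	pruritus
pruritus	trigger	itching
pruritus	trigger	itchy
pruritus	trigger	itchiness
pruritus	trigger	itch
pruritus	trigger	generalized itching
pruritus	trigger	generalized pruritus
weight_loss	trigger	weight loss
weight_loss	trigger	losing weight
weight_loss	trigger	lost weight
weight_loss	trigger	weight down
weight_loss	trigger	unintentional weight loss
weight_loss	trigger	unintended weight loss
anxiety	trigger	anxiety
anxiety	trigger	anxious
anxiety	trigger	panic attack
anxiety	trigger	panic attacks
anxiety	trigger	nervousness
depression	trigger	depression
depression	trigger	depressed
depression	trigger	depressive symptoms
depression	trigger	low mood
depression	trigger	feeling down
insomnia	trigger	insomnia
insomnia	trigger	trouble sleeping
insomnia	trigger	difficulty sleeping
insomnia	trigger	cannot sleep
insomnia	trigger	cant sleep
insomnia	trigger	unable to sleep
insomnia	trigger	sleeplessness
insomnia	trigger	poor sleep
insomnia	trigger	not sleeping well
insomnia	trigger	less sleep
dvt_lower	dvt_location	leg
dvt_lower	dvt_location	legs
dvt_lower	dvt_location	calf
dvt_lower	dvt_location	calves
dvt_lower	dvt_location	thigh
dvt_lower	dvt_location	thighs
dvt_lower	dvt_location	ankle
dvt_lower	dvt_location	ankles
dvt_lower	dvt_location	foot
dvt_lower	dvt_location	feet
dvt_lower	dvt_location	knee
dvt_lower	dvt_location	knees
dvt_lower	dvt_location	shin
dvt_lower	dvt_location	lower extremity
dvt_lower	dvt_location	lower extremities
dvt_lower	dvt_location	lower leg
dvt_lower	dvt_feeling	pain
dvt_lower	dvt_feeling	swollen
dvt_lower	dvt_feeling	swelling
dvt_lower	dvt_feeling	swelled
dvt_lower	dvt_feeling	edema
dvt_lower	dvt_feeling	tender
dvt_lower	dvt_feeling	tenderness
dvt_lower	dvt_feeling	red
dvt_lower	dvt_feeling	redness
dvt_lower	dvt_feeling	warm
dvt_lower	dvt_feeling	warmth
dvt_lower	dvt_feeling	cramping
dvt_lower	dvt_feeling	sore
dvt_lower	dvt_feeling	soreness
dvt_lower	dvt_feeling	heaviness
dvt_lower	dvt_laterality	left
dvt_lower	dvt_laterality	right
dvt_lower	dvt_laterality	bilateral
dvt_lower	dvt_laterality	both
dvt_upper	dvt_location	arm
dvt_upper	dvt_location	arms
dvt_upper	dvt_location	forearm
dvt_upper	dvt_location	forearms
dvt_upper	dvt_location	wrist
dvt_upper	dvt_location	wrists
dvt_upper	dvt_location	hand
dvt_upper	dvt_location	hands
dvt_upper	dvt_location	elbow
dvt_upper	dvt_location	elbows
dvt_upper	dvt_location	upper extremity
dvt_upper	dvt_location	upper extremities
dvt_upper	dvt_location	upper arm
dvt_upper	dvt_feeling	pain
dvt_upper	dvt_feeling	swollen
dvt_upper	dvt_feeling	swelling
dvt_upper	dvt_feeling	swelled
dvt_upper	dvt_feeling	edema
dvt_upper	dvt_feeling	tender
dvt_upper	dvt_feeling	tenderness
dvt_upper	dvt_feeling	red
dvt_upper	dvt_feeling	redness
dvt_upper	dvt_feeling	warm
dvt_upper	dvt_feeling	warmth
dvt_upper	dvt_feeling	cramping
dvt_upper	dvt_feeling	sore
dvt_upper	dvt_feeling	soreness
dvt_upper	dvt_feeling	heaviness
dvt_upper	dvt_laterality	left
dvt_upper	dvt_laterality	right
dvt_upper	dvt_laterality	bilateral
dvt_upper	dvt_laterality	both
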