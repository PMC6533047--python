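canonical_symptom	synonym
exophthalmos	exophthalmos
exophthalmos	bulging eyes
pyrosis	pyrosis
pyrosis	heartburn
hallucination	hallucination
hallucination	hallucinations
hallucination	seeing things
impotence	impotence
impotence	erectile dysfunction
back ache	back ache
back ache	backache
urticaria	urticaria
urticaria	hives
akathisia	akathisia
akathisia	inner restlessness
diaphoresis	diaphoresis
diaphoresis	sweating
diaphoresis	heavy sweating
agoraphobia	agoraphobia
agoraphobia	fear of crowds
cataplexy	cataplexy
bloating	bloating
bloating	bloated stomach
blindness	blindness
blindness	vision loss
amnesia	amnesia
amnesia	memory loss
dizziness	dizziness
dizziness	dizzy
dizziness	lightheaded
anxiety	anxiety
anxiety	anxious
blister	blister
blister	blisters
blurred vision	blurred vision
blurred vision	blurry vision
itch	itch
itch	itching
itch	itchy skin
swelling	swelling
swelling	swollen
tinnitus	tinnitus
tinnitus	ears ringing
tinnitus	ringing in the ears
anorexia	anorexia
anorexia	loss of appetite
cough	cough
cough	coughing
cramp	cramp
cramp	cramps
cramp	muscle cramp
depression	depression
depression	depressed
pain	pain
pain	aching
weight loss	weight loss
weight loss	losing weight
deformity	deformity
paresthesia	paresthesia
paresthesia	skin crawling
paresthesia	pins and needles
diarrhea	diarrhea
diarrhea	loose stools
malaise	malaise
malaise	feeling unwell
phobia	phobia
phobia	phobias
tired	tired
tired	fatigue
tired	exhaustion
constipation	constipation
constipation	constipated
fever	fever
fever	high temperature
back pain	back pain
back pain	lower back pain
rash	rash
rash	skin rash
toothache	toothache
toothache	tooth ache
xerostomia	xerostomia
xerostomia	dry mouth
dysphagia	dysphagia
dysphagia	trouble swallowing
dysphagia	difficulty swallowing
paranoia	paranoia
paranoia	paranoid
perspiration	perspiration
perspiration	perspiring
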