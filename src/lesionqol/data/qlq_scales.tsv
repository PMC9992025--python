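scale_id	label	instrument	direction	r	items
physical_functioning	Physical functioning	C30	functional	3	1,2,3,4,5
role_functioning	Role functioning	C30	functional	3	6,7
emotional_functioning	Emotional functioning	C30	functional	3	21,22,23,24
cognitive_functioning	Cognitive functioning	C30	functional	3	20,25
social_functioning	Social functioning	C30	functional	3	26,27
global_health	Global health status / QoL	C30	global	6	29,30
fatigue	Fatigue	C30	symptom	3	10,12,18
nausea_vomiting	Nausea and vomiting	C30	symptom	3	14,15
pain	Pain	C30	symptom	3	9,19
dyspnoea	Dyspnoea	C30	symptom	3	8
insomnia	Insomnia	C30	symptom	3	11
appetite_loss	Appetite loss	C30	symptom	3	13
constipation	Constipation	C30	symptom	3	16
diarrhoea	Diarrhoea	C30	symptom	3	17
financial_difficulties	Financial difficulties	C30	symptom	3	28
future_uncertainty	Future uncertainty	BN20	symptom	3	31,32,33,35
visual_disorder	Visual disorder	BN20	symptom	3	36,37,38
motor_dysfunction	Motor dysfunction	BN20	symptom	3	40,43,47
communication_deficit	Communication deficit	BN20	symptom	3	44,45,46
headaches	Headaches	BN20	symptom	3	34
seizures	Seizures	BN20	symptom	3	39
drowsiness	Drowsiness	BN20	symptom	3	41
itchy_skin	Itchy skin	BN20	symptom	3	42
hair_loss	Hair loss	BN20	symptom	3	48
weakness_of_legs	Weakness of legs	BN20	symptom	3	49
bladder_control	Bladder control	BN20	symptom	3	50
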