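condition	weight	prefix
myocardial_infarction	1	I21
myocardial_infarction	1	I22
myocardial_infarction	1	I252
congestive_heart_failure	1	I50
peripheral_vascular_disease	1	I70
peripheral_vascular_disease	1	I71
cerebrovascular_disease	1	I60
cerebrovascular_disease	1	I61
cerebrovascular_disease	1	I63
cerebrovascular_disease	1	I64
cerebrovascular_disease	1	G45
dementia	1	F00
dementia	1	F01
dementia	1	F03
dementia	1	G30
chronic_pulmonary_disease	1	J40
chronic_pulmonary_disease	1	J41
chronic_pulmonary_disease	1	J42
chronic_pulmonary_disease	1	J43
chronic_pulmonary_disease	1	J44
chronic_pulmonary_disease	1	J45
chronic_pulmonary_disease	1	J47
rheumatologic_disease	1	M05
rheumatologic_disease	1	M06
rheumatologic_disease	1	M32
rheumatologic_disease	1	M33
rheumatologic_disease	1	M34
peptic_ulcer_disease	1	K25
peptic_ulcer_disease	1	K26
peptic_ulcer_disease	1	K27
peptic_ulcer_disease	1	K28
mild_liver_disease	1	B18
mild_liver_disease	1	K70
mild_liver_disease	1	K73
mild_liver_disease	1	K74
diabetes	1	E10
diabetes	1	E11
diabetes	1	E13
diabetes	1	E14
hemiplegia	2	G81
hemiplegia	2	G82
renal_disease	2	N18
renal_disease	2	N19
renal_disease	2	N03
malignancy	2	C18
malignancy	2	C34
malignancy	2	C50
malignancy	2	C61
malignancy	2	C91
severe_liver_disease	3	I85
severe_liver_disease	3	K72
metastatic_solid_tumor	6	C77
metastatic_solid_tumor	6	C78
metastatic_solid_tumor	6	C79
metastatic_solid_tumor	6	C80
hiv_aids	6	B20
hiv_aids	6	B21
hiv_aids	6	B22
hiv_aids	6	B24
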