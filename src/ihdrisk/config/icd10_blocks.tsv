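system	prefix	group	description
ICD10	I10	hypertensive_diseases	Hypertensive diseases (I10-I16)
ICD10	I11	hypertensive_diseases	Hypertensive diseases (I10-I16)
ICD10	I12	hypertensive_diseases	Hypertensive diseases (I10-I16)
ICD10	I13	hypertensive_diseases	Hypertensive diseases (I10-I16)
ICD10	I15	hypertensive_diseases	Hypertensive diseases (I10-I16)
ICD10	I16	hypertensive_diseases	Hypertensive diseases (I10-I16)
ICD10	I20	ischemic_heart_diseases	Ischemic heart diseases (I20-I25)
ICD10	I21	ischemic_heart_diseases	Ischemic heart diseases (I20-I25)
ICD10	I22	ischemic_heart_diseases	Ischemic heart diseases (I20-I25)
ICD10	I23	ischemic_heart_diseases	Ischemic heart diseases (I20-I25)
ICD10	I24	ischemic_heart_diseases	Ischemic heart diseases (I20-I25)
ICD10	I25	ischemic_heart_diseases	Ischemic heart diseases (I20-I25)
ICD10	I50	heart_failure	Heart failure (I50)
ICD10	E08	diabetes_mellitus	Diabetes mellitus (E08-E13)
ICD10	E09	diabetes_mellitus	Diabetes mellitus (E08-E13)
ICD10	E10	diabetes_mellitus	Diabetes mellitus (E08-E13)
ICD10	E11	diabetes_mellitus	Diabetes mellitus (E08-E13)
ICD10	E13	diabetes_mellitus	Diabetes mellitus (E08-E13)
ICD10	E78	lipoprotein_disorders	Disorders of lipoprotein metabolism (E78)
ICD10	N17	renal_failure	Acute kidney failure and chronic kidney disease (N17-N19)
ICD10	N18	renal_failure	Acute kidney failure and chronic kidney disease (N17-N19)
ICD10	N19	renal_failure	Acute kidney failure and chronic kidney disease (N17-N19)
ICD10	R00	circ_resp_symptoms	Symptoms and signs involving the circulatory and respiratory systems (R00-R09)
ICD10	R01	circ_resp_symptoms	Symptoms and signs involving the circulatory and respiratory systems (R00-R09)
ICD10	R03	circ_resp_symptoms	Symptoms and signs involving the circulatory and respiratory systems (R00-R09)
ICD10	R06	circ_resp_symptoms	Symptoms and signs involving the circulatory and respiratory systems (R00-R09)
ICD10	R07	circ_resp_symptoms	Symptoms and signs involving the circulatory and respiratory systems (R00-R09)
ICD10	R10	abdominal_symptoms	Symptoms and signs involving the digestive system and abdomen (R10-R19)
ICD10	J40	chronic_lower_respiratory	Chronic lower respiratory diseases (J40-J47)
ICD10	J44	chronic_lower_respiratory	Chronic lower respiratory diseases (J40-J47)
ICD10	J45	chronic_lower_respiratory	Chronic lower respiratory diseases (J40-J47)
ICD10	Z00	general_exam	Encounter for general examination (Z00)
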