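system	prefix	group	description
CPT	992	em_office_visits	Evaluation and management, office visits (H2)
CPT	9928	em_consultations	Evaluation and management, consultations (H2)
CPT	80	pathology_lab_panels	Pathology and laboratory, organ/disease panels (H2)
CPT	82	pathology_lab_chemistry	Pathology and laboratory, chemistry (H2)
CPT	83	pathology_lab_chemistry	Pathology and laboratory, chemistry (H2)
CPT	93	cardiovascular_procedures	Medicine, cardiovascular (H2)
CPT	71	radiology_chest	Radiology, chest (H2)
CPT	74	radiology_abdomen	Radiology, gastrointestinal tract / abdomen (H2)
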