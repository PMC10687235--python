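system	prefix	group	description
DRUG	C03	diuretics	Diuretics (ATC C03)
DRUG	C07	beta_blocking_agents	Beta blocking agents (ATC C07)
DRUG	C08	calcium_channel_blockers	Calcium channel blockers (ATC C08)
DRUG	C09	renin_angiotensin_agents	Agents acting on the renin-angiotensin system (ATC C09)
DRUG	C10	lipid_modifying_agents	Lipid modifying agents (ATC C10)
DRUG	A10	drugs_used_in_diabetes	Drugs used in diabetes (ATC A10)
DRUG	B01	antithrombotic_agents	Antithrombotic agents (ATC B01)
DRUG	N02	analgesics	Analgesics (ATC N02)
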