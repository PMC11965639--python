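name	chem_class	source_region
loseolamycin A1	Phenols	1.2
cinerubin B	Anthracyclines	1.16
brasilicardin A	Steroids and steroid derivatives	3.4
pradimicin A	Naphthacenes	3.5
bleomycin A2	Peptidomimetics	3.7
quinolidomycin A	Organooxygen compounds	1.9
kedarcidin	Organooxygen compounds	1.20
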