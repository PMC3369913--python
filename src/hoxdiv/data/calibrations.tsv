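group	age_my	fossil_name	reference
Gastropoda	528	Oelandiella (Latouchella) korobkovi	Khomentovsky & Karlova, 1993
Cephalopoda	520	Plectronoceras	Dzik, 1981
Bivalvia	510	Fordilla troyensis	Pojeta et al., 1973
Crustacea	510	Canadaspis sp.	Briggs, 1978
Insecta	396	Rhyniognatha hirsti	Engel & Grimaldi, 2004
Mammalia Hox-A	195	Hadrocodium wui	Luo et al., 2001
Mammalia Hox-B	195	Hadrocodium wui	Luo et al., 2001
Mammalia Hox-C	195	Hadrocodium wui	Luo et al., 2001
Mammalia Hox-D	195	Hadrocodium wui	Luo et al., 2001
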