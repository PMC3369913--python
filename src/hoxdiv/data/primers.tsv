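pair	name	sequence	orientation	annealing_c	fragment_bp
Dfd1	Dfd1fw	CAAGCGGCAGCGGACNCSNTAYAC	forward	58	160
Dfd1	Dfd1rev	TCTTCCTCCGCACGTTCTTNGTRTTNGG	reverse	57	160
Scr1	Scr1fw	GCAGCGGACCTCCTACACCMGNTAYCARAC	forward	62	128
Scr1	Scr1rev	TCATGGTGGCCATCTTGTGYTCYTTYTTCC	reverse	57	128
Ubx3	Ubx3fw	GCCGGCAGACCTACACCMGNTAYCARAC	forward	61	145
Ubx3	Ubx3rev	CTCCTGCTCGTTCAGCTCYTTDATNGC	reverse	57	145
abdA	abdAfw	CGGCGGCGGGGNMGNCARAC	forward	59	164
abdA	abdArev	GGGCCTGCTCGTTGATCTCYTTNACNGC	reverse	60	164
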