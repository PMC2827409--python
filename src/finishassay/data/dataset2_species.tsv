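species	n_bacs	total_mb
Armadillo	137	18.8
Baboon	110	19.2
Cat	105	14.6
Colobus Monkey	78	16.2
Dusky Titi	88	15.3
Elephant	138	18.8
Galago	99	18.5
Gibbon	83	14.9
Ground Squirrel	89	13.4
Guinea Pig	93	15.6
Hedgehog	130	19.4
Horseshoe Bat	95	15.5
Marmoset	97	19.0
Mouse Lemur	60	13.8
Owl Monkey	88	15.3
Platypus	76	10.8
Rabbit	95	17.4
Shrew	115	15.7
Squirrel Monkey	73	14.6
Tenrec	95	17.1
Vervet Monkey	87	14.5
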