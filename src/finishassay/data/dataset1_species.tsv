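species	taxon	n_bacs	total_mb
Armadillo	Dasypus novemcinctus	25	2.63
Baboon	Papio anubis	15	2.26
Black Lemur	Eulemur macaco macaco	8	1.41
Cat	Felis catus	20	2.11
Chicken	Gallus gallus	7	0.84
Chimpanzee	Pan troglodytes	13	1.73
Colobus Monkey	Colobus guereza	14	2.12
Cow	Bos taurus	15	2.34
Dog	Canis familiaris	9	1.34
Dusky Titi	Callicebus moloch	17	2.29
Elephant	Loxodonta africana	24	2.25
Galago	Otolemur garnettii	13	2.17
Gibbon	Nomascus leucogenys leucogenys	16	2.43
Gorilla	Gorilla gorilla gorilla	11	1.94
Ground Squirrel	Spermophilus tridecemlineatus	16	1.91
Guinea Pig	Cavia porcellus	15	2.01
Hedgehog	Atelerix albiventris	25	2.86
Horse	Equus caballus	14	2.13
Horseshoe Bat	Rhinolophus ferrumequinum	16	1.98
Little Brown Bat	Myotis lucifugus	15	2.16
Macaque	Macaca mulatta	14	1.79
Marmoset	Callithrix jacchus	13	2.13
Mouse Lemur	Microcebus murinus	10	1.76
Orangutan	Pongo pygmaeus	13	2.02
Owl Monkey	Aotus nancymaae	18	2.39
Pig	Sus scrofa	10	1.50
Platypus	Ornithorhynchus anatinus	16	1.68
Rabbit	Oryctolagus cuniculus	17	2.32
Rat	Rattus norvegicus	17	2.16
Ring-tailed Lemur	Lemur catta	10	1.51
Sheep	Ovis aries	15	2.18
Shrew	Sorex araneus	19	2.07
Squirrel Monkey	Saimiri boliviensis boliviensis	15	2.38
Tenrec	Echinops telfairi	12	1.92
Tetraodon	Tetraodon nigroviridis	3	0.32
Torafugu	Takifugu rubripes	2	0.17
Vervet Monkey	Chlorocebus aethiops	13	1.93
Wallaby	Macropus eugenii	16	2.05
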