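region	size_in_human_kb	n_bacs	total_mb
ENm001	1877	357	58.9
ENm003	500	91	15.3
ENm005	1696	256	42.6
ENm010	500	96	16.1
ENm012	1000	179	29.4
ENm013	1114	184	30.3
ENm014	1163	214	35.4
ENr111	500	84	14.4
ENr211	500	89	15.2
ENr213	500	90	15.4
ENr221	500	100	16.5
ENr222	500	98	16.5
ENr312	500	94	15.7
ENr323	500	99	16.9
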