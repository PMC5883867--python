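sample_id	y	covariate
d01	1.529931613457	0
d02	0.653683399577	1
d03	0.762307521222	1
d04	1.133660683321	0
d05	2.106578468624	0
d06	1.784903692004	0
d07	1.848160323005	0
d08	2.244666821386	1
d09	3.175343375440	0
d10	-2.381097744771	0
d11	2.355151856342	1
d12	1.844195725697	1
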