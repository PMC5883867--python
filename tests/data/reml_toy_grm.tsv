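	d01	d02	d03	d04	d05	d06	d07	d08	d09	d10	d11	d12
d01	0.940522977512	-0.127879488349	0.177865155636	0.064359852315	-0.062093957032	0.262360453467	-0.341386303533	-0.112262317709	-0.346502457777	0.156157519097	0.017635306663	0.217751154259
d02	-0.127879488349	0.943317875417	-0.004759041252	-0.054430508074	-0.059916310603	-0.174406033079	-0.090012599869	0.026396748168	0.082161843486	-0.055543340018	-0.015799541382	0.092103637518
d03	0.177865155636	-0.004759041252	0.771526810478	0.055903079354	-0.098227827528	0.156402843778	-0.137959994039	-0.079868456673	-0.113100141410	-0.056863817218	-0.077012462758	0.140594529060
d04	0.064359852315	-0.054430508074	0.055903079354	1.057470474117	0.079147491962	-0.077050829975	-0.109381016463	0.147418122943	-0.011466618080	0.163253745535	-0.172645317118	0.334784844084
d05	-0.062093957032	-0.059916310603	-0.098227827528	0.079147491962	0.791630729658	-0.093459484686	0.037681698838	0.062417604443	0.359486911404	0.063515737359	0.111459870381	-0.081180076908
d06	0.262360453467	-0.174406033079	0.156402843778	-0.077050829975	-0.093459484686	1.241805782088	0.146808379813	-0.197142839559	-0.211215302741	0.204931395637	0.100230225850	0.378026712358
d07	-0.341386303533	-0.090012599869	-0.137959994039	-0.109381016463	0.037681698838	0.146808379813	1.382034913974	0.074975437809	0.150167448813	-0.277150129178	-0.073933848186	0.040485724625
d08	-0.112262317709	0.026396748168	-0.079868456673	0.147418122943	0.062417604443	-0.197142839559	0.074975437809	0.765317505690	-0.168707952267	-0.209839482552	0.105263053301	-0.025898433148
d09	-0.346502457777	0.082161843486	-0.113100141410	-0.011466618080	0.359486911404	-0.211215302741	0.150167448813	-0.168707952267	0.892326096185	0.015852334261	-0.192858768691	-0.074668098547
d10	0.156157519097	-0.055543340018	-0.056863817218	0.163253745535	0.063515737359	0.204931395637	-0.277150129178	-0.209839482552	0.015852334261	1.191873065283	0.000900398995	-0.252673745100
d11	0.017635306663	-0.015799541382	-0.077012462758	-0.172645317118	0.111459870381	0.100230225850	-0.073933848186	0.105263053301	-0.192858768691	0.000900398995	1.107380969399	-0.030808744421
d12	0.217751154259	0.092103637518	0.140594529060	0.334784844084	-0.081180076908	0.378026712358	0.040485724625	-0.025898433148	-0.074668098547	-0.252673745100	-0.030808744421	1.034792800199
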