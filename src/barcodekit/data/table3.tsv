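row	market_name	literature_names	expected_species	family	iucn	similarity_pct	verdict
1	impepo	impepo	Helichrysum sp.	Asteraceae	-	100	True
2	isihlalakahle	?	Harworthia limifolia	Asphodelaceae	Vulnerable (VU)		Amplification failed
3	fembo	?	?	?	-		Amplification failed
4	mkhanya kute	umkhanya-kute;umdlovune;umhlofunga;umhlosinga	Vachellia xanthophloea	Fabaceae	Least Concern (LC)	98	True
5	tindili	umbhone;tindili	Entada rheedii	Fabaceae	Least Concern (LC)	99	True
6	ubhonsi	?	Mappia racemosa	Icacinaceae	Vulnerable (VU)	89	False
7	ukhanyakute	umkhanya-kute;umdlovune;umhlofunga;umhlosinga	Vachellia xanthophloea	Fabaceae	Least Concern (LC)	99	True
8	umlilo	uzililo;ililo elikhulu	Stapelia gigantea	Apocynaceae	Least Concern (LC)	100	True
9	malilisa	?	Holarrhena pubescens	Apocynaceae	Least Concern (LC)	100	False
10	umhlahlawehlathi	umhluswane	Cissus reniferus	Vitaceae	-	97	False
11	mphinde umshaye	?	Adenia gummifera	Passifloraceae	-		False
12	ube nam	umbelebele;umpelepe	Sarcostemma viminale	Asclepiadaceae	Least Concern (LC)	100	False
13	isikholokhota	isikholokhoto	Sanseviera hyacinthiodes	Asparagaceae	Least Concern (LC)	99	True
14	mayime	umayime	Clivia miniata	Amaryllidaceae	Vulnerable (VU)	99	True
15	umdletshane	umbulele;umdletshane	Synadenium cupulare	Euphorbiaceae	Least Concern (LC)	100	True
16	vuka	vuka	Myrothamnus flabellifolius	Myrothamnaceae	DDT	100	True
17	umqotho	incotha;incwadi	Boophane disticha	Amaryllidaceae	Declining	100	True
18	imfingo	imfingo	Stangeria eriopus	Stangeriaceae	Vulnerable (VU)	100	True
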