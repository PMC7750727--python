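itc_code	name	doi	genome	subgroup	collection	origin	cytotype	pattern
ITC0245	Safet Velchi	10.18730/9JM13	AB	Ney Poovan	ITC	India	CaMa	2x-1
ITC1034	Kunnan	10.18730/9M2KD	AB	Ney Poovan	ITC	India	CaMa	2x-2
ITC1747	Agniswar	10.18730/9NGN7	AB	Kunnan	ITC	Indonesia	-	2x-2
ITC1729	Padali Moongil	10.18730/9NFE5	AB	Kunnan	ITC	India	-	2x-3
ITC1752	Poovilla Chundan	10.18730/9NH1K	AB	Kunnan	ITC	India	-	2x-3
ITC1751	Adukka Kunnan	10.18730/9NGYG	AB	Kunnan	ITC	India	-	2x-4
Sum002	Muku Bugis	-	AB	-	ICHORD	Indonesia	-	(2x)
Sum004	Mu'u Seribu	-	AB	-	ICHORD	Indonesia	-	(2x)
ITC1880	Mu'u Pundi	10.18730/P5G84	AB	-	ITC	Indonesia	-	(2x)
ITC1700	Kepok Kuning	10.18730/9ND89	ABB	Saba	ITC	Indonesia	-	N/A
ITC1745	Kepok Tanjung	10.18730/9NGH3	ABB	Saba	ITC	Indonesia	-	N/A
ITC0632	Cachaco enano	10.18730/9KATX	ABB	Bluggoe	ITC	Colombia	-	1a
ITC0643	Cachaco	10.18730/9KBJG	ABB	Bluggoe	ITC	Colombia	-	1a
ITC1728	Sambrani Monthan	10.18730/9NFD4	ABB	Monthan	ITC	India	-	1a
ITC1746	Bankel	10.18730/9NGM6	ABB	Pisang Awak	ITC	India	-	1a
ITC1748	Boddida Bukkisa	10.18730/9NGQ9	ABB	Pisang Awak	ITC	India	-	1a
ITC1483	Monthan	10.18730/9MXQY	ABB	Monthan	ITC	India	CaMb	1a
ITC0026	Sabra	10.18730/9J6SQ	ABB	Unknown	ITC	Gabon	-	1a+
ITC0767	Dole	10.18730/9KGR$	ABB	Bluggoe	ITC	France	CaMb	1a+
ITC0361	Blue Java	10.18730/9JTR~	ABB	Ney Mannan	ITC	Fiji	-	1b
ITC1750	Ney Vannan	10.18730/9NGXF	ABB	Ney Mannan	ITC	India	-	1b
ITC1738	Kyauk Sein Phee Kyan	10.18730/9NG4V	ABB	Unknown	ITC	Myanmar	-	1b
ITC0123	Simili Radjah	10.18730/9JC16	ABB	Peyan	ITC	India	CbMb	1b+
ITC1600	INIVIT PB-2003	10.18730/9N676	ABB	Saba	ITC	Cuba	-	1c
ITC1138	Saba	10.18730/9M6MZ	ABB	Saba	ITC	Philippines	CaMb	1c
ITC0659	Namwa Khom	10.18730/9KCB4	ABB	Pisang Awak	ITC	Thailand	CbMb	2
ITC0053	Bom	10.18730/9J7YQ	ABB	Pisang Awak	ITC	Ivory Coast	-	2
ITC0087	Kayinja	10.18730/9J9YD	ABB	Pisang Awak	ITC	Burundi	-	2
ITC0101	Fougamou 1	10.18730/9JAX7	ABB	Pisang Awak	ITC	Gabon	-	2
ITC0526	Kluai Namwa Khom	10.18730/9K3PQ	ABB	Pisang Awak	ITC	Thailand	-	2
ITC1599	Kambani Zambia	10.18730/9N665	ABB	Pisang Awak	ITC	Tanzania	-	2
ITC1721	Karpuravalli	10.18730/9NEWR	ABB	Pisang Awak	ITC	India	-	2
ITC1737	Ya Khine	10.18730/9NG1R	ABB	Unknown	ITC	Myanmar	-	2
ITC0339	Pisang Awak	10.18730/9JSGY	ABB	Pisang Awak	ITC	Australia	-	2+
ITC1719	Chinia	10.18730/9NERM	ABB	Pisang Awak	ITC	India	-	3
ITC1749	Vananthpurani	10.18730/9NGTC	ABB	Pisang Awak	ITC	India	-	3
ITC0472	Pelipita	10.18730/9K0MU	ABB	Unknown	ITC	Philippines	CaMb	4
ITC0396	Pelipita	10.18730/9JW32	ABB	Unknown	ITC	Costa Rica	-	4
ITC0397	Pelipita Majoncho	10.18730/9JW65	ABB	Unknown	ITC	Costa Rica	-	4
ITC0652	Kluai Tiparot	10.18730/9KC0Y	ABB	Unknown	ITC	Thailand	CbMb	5
ITC0473	Balonkawe	10.18730/9K0P1	ABB	Klue Teparod	ITC	Philippines	-	5
ITC0983	Auko	10.18730/9KZKW	ABB (M)	Unknown	ITC	PNG	-	6
ITC0987	Auko	10.18730/9KZZ3	ABB (M)	Unknown	ITC	PNG	-	6
ITC0990	Vunapope	10.18730/9M06A	ABB (M)	Unknown	ITC	PNG	-	6
ITC1682	Chuoi mit	10.18730/9NC06	ABB (AB)	Unknown	ITC	Vietnam	-	7
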