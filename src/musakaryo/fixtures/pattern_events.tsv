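# Homologous-exchange event sets of the founding patterns described in
# running text (triploid patterns 1a/1b/1c/4/5 and diploid patterns
# 2x-1..2x-4). Arm/terminal-vs-interstitial placement and Ax:By states
# follow the published descriptions; the bp coordinates are SYNTHETIC
# stand-ins chosen to be consistent with the package's default
# chromosome metadata (the source reports locations qualitatively, not
# as coordinates). Patterns 2/3/6/7 are described only graphically and
# are deliberately not encoded.
pattern	baseline_ploidy	chrom	start	end	a_copies	b_copies
1a	3	chr04	22000001	32000000	0	3
1a	3	chr11	17000001	25000000	0	3
1a	3	chr09	5000001	9000000	2	1
1a	3	chr11	1	4000000	0	3
1a	3	chr04	6000001	9000000	2	1
1b	3	chr04	22000001	32000000	0	3
1b	3	chr11	17000001	25000000	0	3
1b	3	chr09	5000001	9000000	2	1
1c	3	chr04	22000001	32000000	0	3
1c	3	chr11	17000001	25000000	0	3
1c	3	chr09	5000001	9000000	2	1
1c	3	chr11	1	4000000	0	3
1c	3	chr02	18000001	24000000	0	3
1c	3	chr04	1	5000000	0	3
1c	3	chr09	11000001	14000000	0	3
4	3	chr02	1	24000000	0	3
4	3	chr11	1	25000000	0	3
4	3	chr07	1	16000000	0	3
4	3	chr07	20000001	29000000	0	3
4	3	chr09	3000001	6000000	2	1
4	3	chr09	24000001	28000000	2	1
5	3	chr02	1	24000000	0	3
5	3	chr08	1	35000000	0	3
5	3	chr10	1	33000000	0	3
5	3	chr03	10000001	18000000	0	3
5	3	chr05	8000001	16000000	0	3
5	3	chr09	11000001	19000000	0	3
2x-1	2	chr06	1	5000000	2	0
2x-2	2	chr08	30000001	35000000	2	0
2x-2	2	chr09	5000001	9000000	2	0
2x-3	2	chr04	1	6000000	2	0
2x-3	2	chr09	5000001	9000000	2	0
2x-4	2	chr09	5000001	9000000	2	0
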