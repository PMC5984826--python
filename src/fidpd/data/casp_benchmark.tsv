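#target	pdb	ligand	binding	length	sites	predicted	tp	no_hit	pli_total	pli_correct
T0652	4HG0	AMP	non-metal	292	11	17	6	0	60	36
T0657	2LUL	ZN	metal	154	5	9	4	0	24	23
T0659	4ESN	ZN	metal	72	3	NA	NA	1	NA	NA
T0675	2LV2	ZN	metal	74	8	9	8	0	30	28
T0686	4HQL	MG	metal	242	5	6	3	0	18	17
T0696	4RT5	NA	metal	111	6	3	1	0	18	15
T0697	4RIT	TRS	non-metal	483	6	11	0	0	104	72
T0706	4RCK	MG	metal	217	5	3	3	0	24	21
T0720	4IC1	MN/SF4	metal	202	14	NA	NA	1	78	58
T0721	4FK1	FAD	non-metal	301	29	3	3	0	60	50
T0726	4FGM	ZN	metal	589	7	NA	NA	1	NA	NA
T0737	3TD7	FAD	non-metal	292	21	13	12	0	72	63
T0744	2YMV	FNR	non-metal	329	19	4	4	0	42	37
T0762	NA	NA	NA	NA	NA	NA	NA	0	42	35
T0764	NA	NA	NA	NA	NA	NA	NA	0	60	52
T0770	NA	NA	NA	NA	NA	NA	NA	0	18	14
T0784	NA	NA	NA	NA	NA	NA	NA	0	18	18
T0854	NA	NA	NA	NA	NA	NA	NA	0	24	20
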