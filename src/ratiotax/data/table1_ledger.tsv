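specimen_id	population	species_group	coi_haplotype	coi_accession	s16_haplotype	s16_accession	its2_haplotype	its2_accession
Ben1	BEN	CLA	COI 1	PP947873	16S 1	PP949387	ITS2 1	PP947951
Ben2	BEN	CLA	COI 1	PP947874	16S 2	PP949388	ITS2 2	PP947952
Ben3	BEN	CLA	COI 2	PP947875	16S 3	PP949389	ITS2 3	PP947953
Ben4	BEN	CLA	COI 3	PP947876	16S 2	PP949390	ITS2 4	PP947954
Ben5	BEN	CLA	COI 3	PP947877	16S 2	PP949391	ITS2 5	PP947955
Ben6	BEN	CLA	COI 3	PP947878	16S 2	PP949392	ITS2 3	PP947956
Gar6	GAR	CLA	COI 4	PP947879	16S 4	PP949393	ITS2 4	PP947957
Gar7	GAR	CLA	COI 5	PP947880	16S 5	PP949394	ITS2 4	PP947958
Gar8	GAR	CLA	COI 6	PP947881	16S 6	PP949395	ITS2 4	PP947959
Gar9	GAR	CLA	COI 7	PP947882	16S 7	PP949396	ITS2 4	PP947960
Gar10	GAR	CLA	COI 8	PP947883	16S 4	PP949397	ITS2 4	PP947961
Mol6	MOL	CLA	COI 1	PP947884	16S 8	PP949398	ITS2 4	PP947962
Mol7	MOL	CLA	COI 1	PP947885	16S 8	PP949399	ITS2 4	PP947963
Mol8	MOL	CLA	COI 9	PP947886	16S 9	PP949400	ITS2 4	PP947964
Mol9	MOL	CLA	COI 3	PP947887	16S 8	PP949401	ITS2 4	PP947965
Mol10	MOL	CLA	COI 3	PP947888	16S 8	PP949402	ITS2 4	PP947966
Mol11	MOL	CLA	COI 3	PP947889	16S 8	PP949403	ITS2 4	PP947967
Pnk1-1	PNK1	PAR-K	COI 10	PP947890	16S 10	PP949404	ITS2 6	PP947968
Pnk1-2	PNK1	PAR-K	COI 11	PP947891	16S 11	PP949405	ITS2 7	PP947969
Pnk1-3	PNK1	PAR-K	COI 11	PP947892	16S 12	PP949406	ITS2 6	PP947970
Pnk1-4	PNK1	PAR-K	COI 11	PP947893	16S 11	PP949407	ITS2 6	PP947971
Pnk1-5	PNK1	PAR-K	COI 11	PP947894	16S 11	PP949408	ITS2 6	PP947972
Bim1-1	BIM1	PAR-K	COI 12	PP947895	16S 13	PP949409	ITS2 8	PP947973
Bim1-2	BIM1	PAR-K	COI 13	PP947896	16S 14	PP949410	ITS2 8	PP947974
Bim1-3	BIM1	PAR-K	COI 14	PP947897	16S 15	PP949411	ITS2 8	PP947975
Bim1-4	BIM1	PAR-K	COI 13	PP947898	16S 16	PP949412	ITS2 8	PP947976
Bim1-5	BIM1	PAR-K	COI 13	PP947899	16S 17	PP949413	ITS2 8	PP947977
Pale1	PAL	PAR-K	COI 15	PP947900	16S 18	PP949414	ITS2 8	PP947978
Pale2	PAL	PAR-K	COI 16	PP947901	16S 19	PP949415	ITS2 8	PP947979
Pale3	PAL	PAR-K	COI 17	PP947902	16S 20	PP949416	ITS2 8	PP947980
Pale4	PAL	PAR-K	COI 13	PP947903	16S 21	PP949417	ITS2 8	PP947981
Pale5	PAL	PAR-K	COI 17	PP947904	16S 20	PP949418	ITS2 8	PP947982
Pale6	PAL	PAR-K	COI 17	PP947905	16S 20	PP949419	ITS2 8	PP947983
Cas-1	CAS	PAR-I		MG208959	16S 22	PP949420	ITS2 9	PP947984
15FG-1	MOL-IT	PAR-I		MG208944	16S 23	PP949421	ITS2 10	PP947985
15FG-2	MOL-IT	PAR-I		MG208947	16S 24	PP949422	ITS2 11	PP947986
Nie-2	NIE	PAR-I		MG208949	16S 25	PP949423
Are-5	ARE	PAR-I		MG208950	16S 26	PP949424	ITS2 9	PP947987
Are-1	ARE	PAR-I		MG208956	16S 26	PP949425	ITS2 9	PP947988
Cur4	CUR	CAR		ON332655		ON350963	ITS2 12	PP947989
Cur5	CUR	CAR	COI 18	PP947906		ON350964	ITS2 13	PP947990
Wro10	WRO	CAR	COI 19	PP947907	16S 27	PP949426	ITS2 14	PP947991
Wro11	WRO	CAR	COI 19	PP947908	16S 27	PP949427	ITS2 14	PP947992
Wro12	WRO	CAR	COI 19	PP947909	16S 27	PP949428	ITS2 14	PP947993
Wro13	WRO	CAR	COI 20	PP947910	16S 28	PP949429	ITS2 14	PP947994
Wro14	WRO	CAR	COI 19	PP947911	16S 27	PP949430	ITS2 14	PP947995
Wro15	WRO	CAR	COI 20	PP947912	16S 29	PP949431	ITS2 14	PP947996
Wro20	WRO	CAR	COI 20	PP947913	16S 27	PP949432	ITS2 14	PP947997
Wro22	WRO	CAR	COI 21	PP947914	16S 27	PP949433	ITS2 14	PP947998
Wro23	WRO	CAR	COI 21	PP947915	16S 27	PP949434	ITS2 14	PP947999
Wro24	WRO	CAR	COI 19	PP947916	16S 27	PP949435	ITS2 14	PP948000
Wro16	WRO	CAR	COI 22	PP947917	16S 30	PP949436	ITS2 14	PP948001
Wro21	WRO	CAR	COI 22	PP947918	16S 38	PP949437	ITS2 14	PP948002
Que1	QUE	CAR	COI 23	PP947919	16S 31	PP949438	ITS2 1	PP948003
Que2	QUE	CAR	COI 24	PP947920	16S 32	PP949439	ITS2 1	PP948004
Que3	QUE	CAR	COI 23	PP947921	16S 31	PP949440	ITS2 1	PP948005
Que4	QUE	CAR	COI 24	PP947922	16S 31	PP949441	ITS2 1	PP948006
Que5	QUE	CAR	COI 25	PP947923	16S 33	PP949442	ITS2 1	PP948007
Pia2	CAN-5	CAN		MK066938	16S 34	PP949443	ITS2 15	PP948008
5FG-1	CAN-6	CAN		MK066944	16S 35	PP949444	ITS2 16	PP948009
5FG-2	CAN-6	CAN		MK066943	16S 36	PP949445	ITS2 16	PP948010
Fio3	FIO	PAN		MT380015	16S 37	PP949446	ITS2 17	PP948011
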