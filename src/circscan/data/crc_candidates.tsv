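circ_id	log2fc	adj_p	host_gene	transcript	genomic_position	db_coding_flag
hsa_circ_0006174	2.96		RAD23B	NM_002874	chr9:110064315-110068928
hsa_circ_0001727	2.05		ZKSCAN1	NM_003439	chr7:99621041-99621930
hsa_circ_0009581	1.95		RERE	NM_012102	chr1:8555122-8601377
hsa_circ_0046430	1.94		FOXK2	NM_004514	chr17:80521229-80545148
hsa_circ_0002702	1.91		RUSC2	NM_001135999	chr9:35546426-35548532
hsa_circ_0000567	1.81		SETD3	NM_199123	chr14:99924615-99932150
hsa_circ_0003098	1.72		BANP	NM_001173542	chr16:88037900-88071617
hsa_circ_0007429	1.71		RREB1	NM_001003699	chr6:7181356-7189555
hsa_circ_0001119	1.69		NDUFA10	NM_004544	chr2:240929490-240954277
hsa_circ_0006528	1.61		PRELID2	NM_138492	chr5:145197456-145205763
hsa_circ_0003026	1.56		USP10	NM_005153	chr16:84773914-84779279
hsa_circ_0063305	1.55		CSNK1E	NM_152221	chr22:38698865-38699253
hsa_circ_0087641	1.49		CDC14B	NM_033331	chr9:99284787-99327765
hsa_circ_0011950	1.48		HIVEP3	NM_024503	chr1:42041214-42050989
hsa_circ_0007144	1.45		PTPRM	NM_001105244	chr18:8076452-8143777
hsa_circ_0006123	1.43		KCNH1	NM_172362	chr1:211092981-211093411
hsa_circ_0001394	1.41		TBC1D14	NM_001113361	chr4:6925099-6925838
hsa_circ_0000725	1.40		BANP	NM_001173539	chr16:88008653-88052273
hsa_circ_0002884	1.33		PICALM	NM_007166	chr11:85692171-85707972
hsa_circ_0012300	1.31		PIK3R3	NM_003629	chr1:46521466-46546422
hsa_circ_0007983	1.31		GABPB1	NM_005254	chr15:50592985-50596330
hsa_circ_0067434	1.31		RYK	NM_001005861	chr3:133894452-133901915
hsa_circ_0007905	1.30		STX6	NM_005819	chr1:180953812-180962561
hsa_circ_0007364	1.28		PTP4A2	NM_080391	chr1:32381495-32385259
hsa_circ_0001573	1.25		RREB1	NM_001168344	chr6:7176887-7189555
hsa_circ_0007015	1.24		PTPN14	NM_005401	chr1:214625147-214638300
hsa_circ_0017726	1.23		DHTKD1	NM_018706	chr10:12123470-12139995
hsa_circ_0000267	1.22		FAM53B	NM_014661	chr10:126370175-126370948
hsa_circ_0004349	1.21		RAC1	NM_018890	chr7:6426842-6431672
hsa_circ_0061774	1.19		BACE2	NM_012105	chr21:42598192-42629253
hsa_circ_0006958	1.19		ACSF3	NM_001243279	chr16:89164998-89169167
hsa_circ_0008199	1.18		ATXN10	NM_013236	chr22:46085591-46136418
hsa_circ_0001513	1.15		LNPEP	NM_005575	chr5:96314841-96322374
hsa_circ_0008812	1.14		RAD23B	NM_002874	chr9:110062421-110074018
hsa_circ_0079958	1.13		HECW1	NM_015052	chr7:43508518-43540921
hsa_circ_0008501	1.12		RERE	NM_012102	chr1:8601272-8674745
hsa_circ_0088865	1.09		SPTAN1	NM_001130438	chr9:131365821-131367756
hsa_circ_0004853	1.07		CD97	NM_078481	chr19:14513408-14515374
hsa_circ_0067080	1.06		ITGB5	NM_002213	chr3:124560229-124592378
hsa_circ_0008826	1.06		DHTKD1	NM_018706	chr10:12136071-12162266
hsa_circ_0009006	1.05		LDB2	NM_001130834	chr4:16587544-16597498
hsa_circ_0006088	1.05		SPTAN1	NM_001130438	chr9:131362358-131367756
hsa_circ_0002153	1.03		MID2	NM_012216	chrX:107083899-107097934
hsa_circ_0000504	1.02		TUBGCP3	NM_006322	chr13:113170753-113181798
hsa_circ_0003273	1.02		TRIP12	NM_004238	chr2:230723487-230744844
hsa_circ_0036408	1.00		ETFA	NM_000126	chr15:76580186-76588078
hsa_circ_0005654	-1.04		PRDM5	NM_018699	chr4:121675707-121732604
hsa_circ_0087897	-1.15		C9orf5	NM_032012	chr9:111795586-111870850
hsa_circ_0047814	-1.23		ZNF532	NM_018181	chr18:56585502-56587865
hsa_circ_0005927	-1.25		VDAC3	NM_001135694	chr8:42259305-42260979
hsa_circ_0029976	-1.37		NBEA	NM_015678	chr13:35615069-35644989
hsa_circ_0003250	-1.38		MRRF	NM_138777	chr9:125042721-125054119
hsa_circ_0000370	-1.52		FLI1	NM_002017	chr11:128628009-128651918
hsa_circ_0034762	-1.57		MAPKBP1	NM_001128608	chr15:42103080-42105299
hsa_circ_0009580	-1.65		RERE	NM_012102	chr1:8555122-8568734
hsa_circ_0042435	-1.76		SPECC1	NM_001243439	chr17:20149238-20209395
hsa_circ_0043278	-5.12		TADA2A	NM_001488	chr17:35797838-35800763
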