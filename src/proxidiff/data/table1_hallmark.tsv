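hallmark	size	direction_idiopathic	nes_idiopathic	q_idiopathic	direction_ischemic	nes_ischemic	q_ischemic	proteins
ADIPOGENESIS	176	up	1.11	0.420844	down	-1.20	0.169207	DBT,TST,MDH2
ALLOGRAFT_REJECTION	197	down	-1.05	0.394748	up	1.07	0.487176	RPS9,MAP3K7
ANDROGEN_RESPONSE	98	down	-1.83	0.001006	down	-1.90	5.31e-4	SRP19,SGK1
ANGIOGENESIS	35	up	1.21	0.27238	up	1.24	0.252174
APICAL_JUNCTION	178	down	-1.07	0.375625	down	-1.02	0.461531	LIMA1,GTF2F1,EPB41L2,TSC1
APOPTOSIS	157	down	-1.51	0.018923	down	-1.40	0.044813	LMNA,ANXA1,CASP1,CASP4,CASP3,PPT1,BID,BNIP3L,SPTAN1
BILE_ACID_METABOLISM	99	up	1.74	0.009496	up	1.62	0.01886	PRDX5,ATXN1
CHOLESTEROL_HOMEOSTASIS	61	down	-1.32	0.074947	down	-1.28	0.104645	ANXA5
COAGULATION	134	up	1.42	0.075674	up	1.59	0.018179	ANXA1,CSRP1
COMPLEMENT	186	down	-1.44	0.028868	down	-1.33	0.0762	CASP1,CASP4,CASP3,ANXA5,PRSS3,CSRP1
DNA_REPAIR	135	down	-0.93	0.655048	down	-1.01	0.458158	REV3L,EDF1,CETN2,NME3,GTF2F1,RFC2,RFC3,HPRT1,TP53
E2F_TARGETS	187	down	-1.57	0.012377	down	-1.50	0.026689	RFC2,RFC3,PSIP1,CBX5,NUP153,PNN,TMPO,STMN1,NASP,RACGAP1,TP53
EPITHELIAL_MESENCHYMAL_TRANSITION	192	up	1.53	0.031229	up	1.82	0.005753	TAGLN
ESTROGEN_RESPONSE_EARLY	198	down	-1.58	0.012051	down	-1.64	0.006863	DHRS2,SVIL
ESTROGEN_RESPONSE_LATE	199	down	-1.49	0.019649	down	-1.49	0.025326	TST,HPRT1,DHRS2,SGK1
FATTY_ACID_METABOLISM	145	up	1.09	0.438963	down	-1.15	0.224652	MDH2,ACADVL,UROD,MIF
G2M_CHECKPOINT	195	down	-1.52	0.017902	down	-1.48	0.027784	NCL,SFPQ,TMPO,STMN1,NASP,TOP1,KIF23,TPX2,RACGAP1
GLYCOLYSIS	186	up	1.02	0.49266	up	1.16	0.35265	MDH2,STMN1,NASP,MIF,PGK1,PC
HEME_METABOLISM	194	up	1.02	0.524825	up	0.98	0.637137	UROD,TOP1,CAST,YPEL5,HEBP1,BNIP3L,HDGF,PC,ASNS
HYPOXIA	192	down	-1.77	0.002004	down	-1.56	0.013079	NAGK,BNIP3L,PRDX5,MIF,PGK1,FOSL2,KLF6
IL2_STAT5_SIGNALING	177	down	-1.50	0.019949	down	-1.45	0.030848	CASP3,KLF6,PHLDA1
IL6_JAK_STAT3_SIGNALING	86	down	-1.84	8.15e-4	down	-1.62	0.00786	IRF9
INFLAMMATORY_RESPONSE	194	down	-1.83	0.001168	down	-1.69	0.004573	KLF6
INTERFERON_ALPHA_RESPONSE	80	up	1.73	0.007606	up	1.78	0.004291	CASP1,IRF9,TRIM21,IFI44,SP110,IFIH1
INTERFERON_GAMMA_RESPONSE	177	up	1.27	0.201025	up	1.41	0.070512	CASP1,CASP4,CASP3,IRF9,TRIM21,IFI44,SP110,IFIH1
KRAS_SIGNALING_DN	195	up	0.86	0.829231	up	0.87	0.871536	KMT2D,SGK1
KRAS_SIGNALING_UP	196	down	-1.06	0.38636	up	1.01	0.630874	WDR33
MITOTIC_SPINDLE	181	down	-1.21	0.160671	down	-1.25	0.127236	PCNT,CAPZB,PCM1,RANBP9,CD2AP,EPB41L2,TSC1,SPTAN1,KIF23,TPX2,RACGAP1,APC
MTORC1_SIGNALING	193	down	-2.35	0	down	-2.31	0	HPRT1,PGK1,PSMC2,ATP6V1D,ASNS
MYC_TARGETS_V1	189	down	-2.18	0	down	-2.27	0	HPRT1,PGK1,HNRNPC,EEF1B2,GLO1,C1QBP,PWP1,SF3A1,SERBP1,MRPL9,HDGF,CBX3,PHB2
MYC_TARGETS_V2	55	down	-2.16	0	down	-2.13	0	CBX3,TCOF1
MYOGENESIS	197	up	1.39	0.080993	up	1.21	0.276254	SVIL,SPTAN1,FHL1,TAGLN,PC
NOTCH_SIGNALING	28	up	0.91	0.762965	down	-0.77	0.923318	PPARD
OXIDATIVE_PHOSPHORYLATION	194	up	1.82	0.004724	up	1.45	0.059126	MDH2,ACADVL,ATP6V1D,PHB2,NDUFB3,OPA1,NDUFB6,NQO2,NDUFV1
P53_PATHWAY	195	down	-1.61	0.01035	down	-1.47	0.028355	CASP1,DNTTIP2,TP53
PEROXISOME	96	up	1.18	0.309822	up	0.99	0.658104	PRDX5,VPS4B,ATXN1
PI3K_AKT_MTOR_SIGNALING	100	down	-1.79	0.001342	down	-1.68	0.004535	CFL1,ECSIT,PIKFYVE,MAP3K7
PROTEIN_SECRETION	95	down	-1.28	0.096338	down	-1.39	0.04544	PPT1,SNX2,ARFGAP3,VPS4B
REACTIVE_OXYGEN_SPECIES_PATHWAY	44	down	-1.63	0.008859	down	-1.63	0.007414	PDLIM1
SPERMATOGENESIS	124	up	0.84	0.81949	up	0.72	1	PEBP1,ZC3H14
TGF_BETA_SIGNALING	51	down	-1.59	0.011077	down	-1.68	0.005039	APC,MAP3K7
TNFA_SIGNALING_VIA_NFKB	195	down	-2.50	0	down	-2.26	0	NFKB2,TRIP10,SGK1,FOSL2,KLF6,PHLDA1,IFIH1
UNFOLDED_PROTEIN_RESPONSE	108	down	-2.20	0	down	-2.28	0	PARN,BAG3,FUS,EIF4A3,DCP2,KHSRP,ASNS
UV_RESPONSE_DN	140	up	1.09	0.409433	up	1.11	0.41775	SIPA1L1,RND3,PHF3,ATXN1
UV_RESPONSE_UP	155	down	-1.98	0	down	-1.96	0	TST,CASP3,PPT1,BID,UROD,ASNS,EIF5,CDC5L
WNT_BETA_CATENIN_SIGNALING	37	down	-0.87	0.783655	down	-0.88	0.759333	TP53,PPARD
XENOBIOTIC_METABOLISM	187	down	-1.41	0.035226	down	-1.47	0.028478	HPRT1,PC,PPARD
APICAL_SURFACE	34	down	-0.94	0.655474	down	-1.00	0.471533
HEDGEHOG_SIGNALING	36	up	1.03	0.541695	up	0.96	0.646984
PANCREAS_BETA_CELLS	40	down	-0.53	0.998829	up	0.57	0.998143
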