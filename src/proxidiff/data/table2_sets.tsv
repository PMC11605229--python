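gene_set	regulation	proteins
MYC_TARGETS_V1	down	HPRT1,PGK1,HNRNPC,EEF1B2,GLO1,C1QBP,PWP1,SF3A1,SERBP1,MRPL9,HDGF,CBX3,PHB2
E2F_TARGETS	down	RFC2,RFC3,PSIP1,CBX5,NUP153,PNN,TMPO,STMN1,NASP,RACGAP1,TP53
G2M_CHECKPOINT	down	NCL,SFPQ,TMPO,STMN1,NASP,TOP1,KIF23,TPX2,RACGAP1
P53_PATHWAY	down	CASP1,DNTTIP2,TP53
APOPTOSIS	down	LMNA,ANXA1,CASP1,CASP4,CASP3,PPT1,BID,BNIP3L,SPTAN1
HYPOXIA	down	NAGK,BNIP3L,PRDX5,MIF,PGK1,FOSL2,KLF6
XENOBIOTIC_METABOLISM	down	HPRT1,PC,PPARD
UV_RESPONSE_UP	down	TST,CASP3,PPT1,BID,UROD,ASNS,EIF5,CDC5L
UNFOLDED_PROTEIN_RESPONSE	down	PARN,BAG3,FUS,EIF4A3,DCP2,KHSRP,ASNS
TNFA_SIGNALING_VIA_NFKB	down	NFKB2,TRIP10,SGK1,FOSL2,KLF6,PHLDA1,IFIH1
MTORC1_SIGNALING	down	HPRT1,PGK1,PSMC2,ATP6V1D,ASNS
ESTROGEN_RESPONSE_LATE	down	TST,HPRT1,DHRS2,SGK1
PI3K_AKT_MTOR_SIGNALING	down	CFL1,ECSIT,PIKFYVE,MAP3K7
IL2_STAT5_SIGNALING	down	CASP3,KLF6,PHLDA1
INTERFERON_ALPHA_RESPONSE	up	CASP1,IRF9,TRIM21,IFI44,SP110,IFIH1
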