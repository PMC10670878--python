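protein_id	regulons
SPOIIQ	SigF
SSPB	SigF
GPR	SigF
SPOIVB	SigF
RSFA	SigF
SSPA	SigG
SSPE	SigG
SLEB	SigG
PDAA	SigG
YHCN	SigG
SPOIID	SigE
SPOIIIA	SigE
SPOIVA	SigE
COTE	SigE
YABP	SigE
SPOVID	SigE
COTA	SigK
COTB	SigK
COTC	SigK
GERE	SigK
CITZ	SigA
CITB	SigA
ICD	SigA
MDH	SigA
ARGG	SigA
ARGH	SigA
SPO0A_TGT	Spo0A
KINA	SigH
SPOIIAA	SigH,SigF
YDFS	SigF,SigE
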