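chr3	187439163	187463513	BCL6	OCG
chr3	178866309	178952497	PIK3CA	OCG
chr8	128748313	128753680	MYC	OCG
chr8	141668479	142011412	PTK2	PPA
chr12	25358178	25403854	KRAS	OCG
chr19	45251976	45263301	BCL3	OCG
chr19	45281124	45303903	CBLC	OCG
chr19	40736222	40791302	AKT2	OCG
chr19	39390338	39399534	NFKBIB	PPA
chr19	39078279	39108643	MAP4K1	PPA
chr19	39876268	39881835	PAF1	PPA
chr19	38924338	39078204	RYR1	PPA
chr9	4985243	5128183	JAK2	OCG
chr9	21802633	21865969	MTAP	TSG
chr9	21967749	21994490	CDKN2A	TSG
chr9	22002900	22009312	CDKN2B	TSG
chr9	8314244	10612723	PTPRD	TSG
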