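gene	ARNTL	NPAS2	CLOCK	NR1D1	NR1D2	DBP	TEF	HLF	PER3	PER1	BHLHE40	CRY2	BHLHE41	PER2	CRY1	RORC	NFIL3
ARNTL	1.0	0.93353	0.829192	-0.036691	-0.226336	-0.887489	-0.922147	-0.94614	-0.953871	-0.971008	-0.973286	-0.937366	-0.909638	-0.871741	-0.005506	0.187671	0.680117
NPAS2	0.93353	1.0	0.893574	0.247042	0.057384	-0.716667	-0.778299	-0.829545	-0.835025	-0.881512	-0.913909	-0.967034	-0.971186	-0.962096	-0.286217	-0.096144	0.44714
CLOCK	0.829192	0.893574	1.0	0.324114	0.14626	-0.5997	-0.665154	-0.716214	-0.722192	-0.771598	-0.811154	-0.883091	-0.897427	-0.89749	-0.35957	-0.178449	0.336405
NR1D1	-0.036691	0.247042	0.324114	1.0	0.965016	0.439266	0.350127	0.259102	0.261858	0.165897	0.071204	-0.209353	-0.304677	-0.395492	-0.976484	-0.957848	-0.700289
NR1D2	-0.226336	0.057384	0.14626	0.965016	1.0	0.603729	0.523666	0.438647	0.441499	0.351408	0.261359	-0.018129	-0.116991	-0.212106	-0.944515	-0.967721	-0.821728
DBP	-0.887489	-0.716667	-0.5997	0.439266	0.603729	1.0	0.979769	0.957395	0.965751	0.93656	0.896246	0.736892	0.670707	0.5961	-0.399539	-0.566712	-0.911928
TEF	-0.922147	-0.778299	-0.665154	0.350127	0.523666	0.979769	1.0	0.97096	0.979244	0.960151	0.92901	0.795025	0.737896	0.668969	-0.30938	-0.486034	-0.872002
HLF	-0.94614	-0.829545	-0.716214	0.259102	0.438647	0.957395	0.97096	1.0	0.978218	0.970278	0.947422	0.842817	0.793699	0.734362	-0.217443	-0.401509	-0.821737
PER3	-0.953871	-0.835025	-0.722192	0.261858	0.441499	0.965751	0.979244	0.978218	1.0	0.979007	0.955279	0.848036	0.799356	0.7386	-0.219596	-0.402848	-0.827272
PER1	-0.971008	-0.881512	-0.771598	0.165897	0.351408	0.93656	0.960151	0.970278	0.979007	1.0	0.969019	0.891515	0.850693	0.798941	-0.12336	-0.31108	-0.769743
BHLHE40	-0.973286	-0.913909	-0.811154	0.071204	0.261359	0.896246	0.92901	0.947422	0.955279	0.969019	1.0	0.919517	0.89019	0.848903	-0.029341	-0.220199	-0.704131
CRY2	-0.937366	-0.967034	-0.883091	-0.209353	-0.018129	0.736892	0.795025	0.842817	0.848036	0.891515	0.919517	1.0	0.961302	0.94971	0.248805	0.056938	-0.479519
BHLHE41	-0.909638	-0.971186	-0.897427	-0.304677	-0.116991	0.670707	0.737896	0.793699	0.799356	0.850693	0.89019	0.961302	1.0	0.968818	0.343143	0.155059	-0.392823
PER2	-0.871741	-0.962096	-0.89749	-0.395492	-0.212106	0.5961	0.668969	0.734362	0.7386	0.798941	0.848903	0.94971	0.968818	1.0	0.432641	0.248923	-0.304392
CRY1	-0.005506	-0.286217	-0.35957	-0.976484	-0.944515	-0.399539	-0.30938	-0.217443	-0.219596	-0.12336	-0.029341	0.248805	0.343143	0.432641	1.0	0.941419	0.665434
RORC	0.187671	-0.096144	-0.178449	-0.957848	-0.967721	-0.566712	-0.486034	-0.401509	-0.402848	-0.31108	-0.220199	0.056938	0.155059	0.248923	0.941419	1.0	0.789267
NFIL3	0.680117	0.44714	0.336405	-0.700289	-0.821728	-0.911928	-0.872002	-0.821737	-0.827272	-0.769743	-0.704131	-0.479519	-0.392823	-0.304392	0.665434	0.789267	1.0
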