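rna_type	regulated	fc_meth_ratio	p_meth	gene_symbol	locus
lncRNA	hypo	0.666631912	0.001001122	RP4-651E10.4	chr1:87,036,864–87,170,176:-
lncRNA	hypo	0.666561648	0.002866294	RP11-552F3.10	chr17:73,893,141–73,896,229:+
lncRNA	hypo	0.66615389	0.043268439	PRIMPOL	chr4:185,570,767–185,616,113:+
lncRNA	hypo	0.666014095	0.036625819	FAM185A	chr7:102,389,399–102,449,672:+
lncRNA	hypo	0.665494975	0.007337869	RP11-378I13.1	chr1:57,289,352–57,292,593:-
lncRNA	hypo	0.665279091	0.00670786	AMPH	chr7:38,431,589–38,468,885:-
lncRNA	hypo	0.665043357	0.02109388	PTPN21	chr14:88,959,244–89,017,833:-
lncRNA	hypo	0.664971159	0.001343962	CTD-2382E5.1	chr15:42,264,961–42,291,292:+
lncRNA	hypo	0.664702615	0.029267432	RP11-58H15.4	chr4:144,434,625–144,435,788:-
lncRNA	hypo	0.664663218	0.010643021	PRM2	chr16:11,369,493–11,370,337:-
pri-miRNA	hypo	0.666116893	0.016809979	pri-5-hsa-mir-6738	chr1:155,921,117–155,921,217:-
pre-miRNA	hypo	0.665986206	0.045864605	hsa-mir-6820	chr22:38,363,570–38,363,631:+
pri-miRNA	hypo	0.665974655	0.01367578	pri-5-hsa-mir-6857	chrX:53,432,687–53,432,787:-
pre-miRNA	hypo	0.665876082	0.023250338	hsa-mir-130b	chr22:22,007,593–22,007,674:+
pri-miRNA	hypo	0.665669961	0.036412869	pri-3-hsa-mir-5694	chr14:67,908,482–67,908,582:-
pre-miRNA	hypo	0.665343126	0.019019336	hsa-mir-6814	chr21:43,166,932–43,167,001:-
snoRNA	hypo	0.663864549	0.003881281	RF00322	chr14:42,063,666–42,063,794:+
pri-miRNA	hypo	0.663166661	0.005558968	pri-3-hsa-mir-4675	chr10:20,840,965–20,841,065:+
pre-miRNA	hypo	0.662849078	0.019664973	hsa-mir-609	chr10:105,978,547–105,978,641:-
pri-miRNA	hypo	0.662250133	0.010265539	pri-3-hsa-mir-4529	chr18:53,146,519–53,146,619:+
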