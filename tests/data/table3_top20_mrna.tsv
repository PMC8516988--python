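gene_symbol	regulation	fc_m6a_log2	fc_ge_log2	locus
BCL2A1	Hypo-down	-3.1482429	-0.873422863	chr15:80,253,234–80,263,511:-
CD93	Hypo-down	-3.0826079	-2.790594724	chr20:23,059,986–23,066,977:-
ARHGAP4	Hypo-down	-3.0612382	-1.397050765	chrX:153,172,831–153,191,698:-
SUSD1	Hypo-down	-2.8111023	-0.646360165	chr9:114,803,065–114,937,688:-
MYO1F	Hypo-down	-2.765078	-2.551049185	chr19:8,585,674–8,642,331:-
SLA	Hypo-down	-2.7599988	-3.59682397	chr8:134,049,898–134,115,156:-
TOM1	Hypo-down	-2.6615412	-2.495029988	chr22:35,695,797–35,743,987:+
ARSG	Hypo-down	-2.5774009	-0.852254218	chr17:66,255,323–66,418,872:+
MEFV	Hypo-down	-2.574598	-1.736043206	chr16:3,292,028–3,306,627:-
G0S2	Hypo-down	-2.5421099	-5.958020173	chr1:209,848,765–209,849,733:+
RP11-80B17.1	Hypo-up	-3.8966634	3.489528549	chr3:161,214,596–161,221,730:+
TLR10	Hypo-up	-3.7814104	3.013192068	chr4:38,773,860–38,784,611:-
TTC30B	Hypo-up	-3.7168964	4.747257284	chr2:178,413,726–178,417,742:-
PAM	Hypo-up	-3.4721222	2.95986846	chr5:102,201,714–102,364,814:+
UACA	Hypo-up	-3.3243618	3.019706944	chr15:70,949,141–70,994,647:-
DDX58	Hypo-up	-3.2698532	2.377325024	chr9:32,455,300–32,502,734:-
GOLGA1	Hypo-up	-3.2181953	2.705210092	chr9:127,640,636–127,703,378:-
ADCY3	Hypo-up	-3.2063213	2.140407984	chr2:25,042,041–25,142,055:-
CHRNA1	Hypo-up	-3.1912752	3.351292425	chr2:175,612,388–175,629,189:-
LIPF	Hypo-up	-3.1811642	2.530582545	chr10:90,424,215–90,438,571:+
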