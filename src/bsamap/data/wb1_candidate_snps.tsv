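delta	gene_id	chrom	pos	ref	alt	mutation_type	annotation
0.758	ORF1	chr04	21550665	T	G	Missense (T to P)	Helicase conserved C-terminal domain containing protein
0.754	ORF1	chr04	21550664	G	T	Missense (T to K)	Helicase conserved C-terminal domain containing protein
0.663	ORF1	chr04	21550888	C	T	Intron mutation	Helicase conserved C-terminal domain containing protein
0.655	ORF1	chr04	21550286	T	A	Missense (T to S)	Helicase conserved C-terminal domain containing protein
0.649	ORF1	chr04	21551279	G	A	Intron mutation	Helicase conserved C-terminal domain containing protein
0.754	ORF2	chr04	21539737	A	G	3'-UTR mutation	Protein of unknown function DUF668 family protein
0.612	ORF2	chr04	21539457	G	T	Splice region mutation	Protein of unknown function DUF668 family protein
0.743	ORF3	chr04	21331260	G	A	Missense (D to N)	40S ribosomal protein S10
0.734	ORF4	chr04	21514382	C	T	Intron mutation	Similar to H0315E07.10 protein
0.708	ORF4	chr04	21513793	A	G	Intron mutation	Similar to H0315E07.10 protein
0.734	ORF5	chr04	21612944	C	A	Missense (K to N)	CENP-E-like kinetochore protein
0.663	ORF5	chr04	21610862	C	A	Missense (S to I)	CENP-E-like kinetochore protein
0.733	ORF6	chr04	20423829	G	A	Missense (A to T)	Glycosyl hydrolases
0.733	ORF7	chr04	21795109	G	A	Missense (L to F)	Expressed protein
0.672	ORF8	chr04	21493980	G	A	Intron mutation	Similar to H0315E07.7 protein
0.639	ORF9	chr04	21897538	C	T	3'-UTR mutation	Nonsense-mediated decay UPF3
0.634	ORF10	chr04	21970357	C	T	5'-UTR mutation	Peptide transporter PTR2
0.631	ORF11	chr04	21710470	C	G	Intron mutation	Conserved hypothetical protein
0.61	ORF12	chr04	21734385	C	T	Nonsense (R to *)	No apical meristem protein
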