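yeast_gene	human_gene	source	confidence
YDL185W	ATP6V1A	ensembl	9.0
YDL185W	ATP6V1B1	diopt	5.0
YKL080W	ATP6V1E1	ensembl	8.0
YPL234C	ATP6V0C	ensembl	7.0
YBR127C	ATP6V1B2	ensembl	9.0
YDR377W	ATP6V1F	diopt	6.0
YEL027W	ATP6V0B	ensembl	7.0
YOR332W	ATP6V0D1	diopt	4.0
YHR026W	ATP6V0A1	ensembl	6.0
YGR020C	ATP6V1G1	ensembl	5.0
YMR058W	HEPH	ensembl	3.0
YMR058W	CP	diopt	3.0
YLR447C	ATP6V0A2	ensembl	5.0
YDR155C	PPIA	ensembl	9.0
YBR106W	SURF4	ensembl	8.0
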