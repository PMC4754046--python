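Variation	Source (allele count)	Location (GRCh37)	Ref/alt	Predicted amino acid change
Population	ExAC (1)	chr3:176768368	C/T	Gly153Glu
Population	dbSNP	chr3:176768338	A/G	Val163Ala
Population	ExAC (1)	chr3:176768288	C/T	Val180Ile
Population	ExAC (1)	chr3:176767892	T/A	Ser199Cys
Population	ExAC (1)	chr3:176767879	G/C	Thr203Ser
Diagnostic	DDD	chr3:176767848	A/T	His213Gln
Population	ExAC (1)	chr3:176765173	C/T	Ser260Asn
Population	dbSNP	chr3:176765158	T/C	His265Arg
Diagnostic	O'Roak et al.	chr3:176765107	A/G	Leu282Pro
Population	ExAC (1)	chr3:176756189	T/C	Asn320Ser
Population	dbSNP	chr3:176756189	T/G	Asn320Thr
Population	EVA	chr3:176756187	T/C	Thr321Ala
Diagnostic	DDD	chr3:176756165	T/C	Asp328Gly
Population	ExAC (1)	chr3:176756102	G/T	Thr349Lys
Population	ExAC (2)	chr3:176755930	T/C	Thr360Ala
Population	dnSNP	chr3:176755930	T/A	Thr360Ser
Population	ExAC (1)	chr3:176755923	T/G	Asn362Thr
Diagnostic	DDD	chr3:176755900	C/A	Asp370Tyr
Population	ExAC (1)	chr3:176752065	T/C	Asn391Asp
Population	ExAC (2)	chr3:176752022	C/T	Gly405Glu
Population	ExAC (5)	chr3:176752016	T/C	Asn407Ser
Population	dbSNP	chr3:176752017	T/C	Asn407Asp
Population	ExAC (1)	chr3:176752014	T/C	Asn408Asp
Population	ExAC (1)	chr3:176750916	A/C	Phe420Cys
Population	ExAC (1)	chr3:176750908	T/C	Thr423Ala
Population	ExAC (1)	chr3:176750905	C/G	Val424Leu
Population	ExAC (1)	chr3:176750884	G/C	Arg431Gly
Population	dbSNP	chr3:176750883	C/T	Arg431Gln
Population	dbSNP	chr3:176750860	T/C	Thr439Ala
Population	dbSNP	chr3:176750855	T/G	Lys440Asn
Diagnostic	DDD	chr3:176750853	T/C	His441Arg
Diagnostic	DDD	chr3:176750844	G/C	Pro444Arg
Population	ExAC (1)	chr3:176750817	T/C	Asp453Gly
Population	ExAC (2)	chr3:176750811	C/T	Arg455Lys
Population	ExAC (27)	chr3:176744255	G/A	Ala475Val
Population	ExAC (1)	chr3:176744247	G/C	His478Asp
Population	ExAC (1)	chr3:176744189	T/C	Lys497Arg
Population	dbSNP	chr3:176743294	G/A	Arg513Trp
Population	ExAC (1)	chr3:176743291	T/G	Lys514Gln
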