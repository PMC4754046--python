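Variation	Source (allele count)	Location (GRCh37)	Ref/alt	Predicted amino acid change
Diagnostic	DDD		 	p.(His441Arg)
Diagnostic	DDD		 	p.(Asp370Tyr)
Diagnostic	DDD		 	p.(Asp328Gly)
Diagnostic	DDD		 	p.(Pro444Arg)
Diagnostic	DDD		 	p.(His213Gln)
Diagnostic	Saitsu et al.		 	p.(Gly70Asp)
Diagnostic	O'Roak et al.		 	p.(Leu282Pro)
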