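# Standard genetic code: codon <TAB> label (three-letter amino acid or STOP)
TTT	Phe
TTC	Phe
TTA	Leu
TTG	Leu
CTT	Leu
CTC	Leu
CTA	Leu
CTG	Leu
ATT	Ile
ATC	Ile
ATA	Ile
ATG	Met
GTT	Val
GTC	Val
GTA	Val
GTG	Val
TCT	Ser
TCC	Ser
TCA	Ser
TCG	Ser
CCT	Pro
CCC	Pro
CCA	Pro
CCG	Pro
ACT	Thr
ACC	Thr
ACA	Thr
ACG	Thr
GCT	Ala
GCC	Ala
GCA	Ala
GCG	Ala
TAT	Tyr
TAC	Tyr
TAA	STOP
TAG	STOP
CAT	His
CAC	His
CAA	Gln
CAG	Gln
AAT	Asn
AAC	Asn
AAA	Lys
AAG	Lys
GAT	Asp
GAC	Asp
GAA	Glu
GAG	Glu
TGT	Cys
TGC	Cys
TGA	STOP
TGG	Trp
CGT	Arg
CGC	Arg
CGA	Arg
CGG	Arg
AGT	Ser
AGC	Ser
AGA	Arg
AGG	Arg
GGT	Gly
GGC	Gly
GGA	Gly
GGG	Gly
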