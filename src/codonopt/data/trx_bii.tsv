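# Dinucleotide flexibility scale: percent of time the phosphate linkage of the
# step M-N spends in the BII backbone conformation (0 = stiff / entirely BI,
# 43 = very flexible / nearly half time in each substate).
# Transcribed from the published experimental scale; values are assigned per
# complementary step, so a dinucleotide and its reverse complement share a value.
AA	13
AC	4
AG	8
AT	0
CA	25
CC	43
CG	13
CT	8
GA	36
GC	43
GG	43
GT	4
TA	13
TC	36
TG	25
TT	13
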