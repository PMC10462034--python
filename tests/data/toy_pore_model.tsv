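kmer	level_mean	level_stdv
AA	70.0	2.0
AC	80.0	2.0
AG	75.0	2.0
AT	85.0	2.0
CA	90.0	2.0
CC	100.0	2.0
CG	95.0	2.0
CT	105.0	2.0
GA	72.0	2.0
GC	82.0	2.0
GG	77.0	2.0
GT	87.0	2.0
TA	92.0	2.0
TC	102.0	2.0
TG	97.0	2.0
TT	107.0	2.0
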