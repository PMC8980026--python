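name	sequence	max_sub	max_indel
CSB-F	ATGTAGTAAGAACCTACCAAGGG	9	2
CSB-E	ACAACTATTGTGGGG	9	2
CSB-D	GTTATTCCTGGCATTTGGTTCCTA	9	2
CSB-1	CATATTAGGATATCAAGAGCATAA	9	2
CSB-2	GTAAAACCCCCCTACCCCCC	9	2
CSB-3	TCCTGAAAACCCCCCGGAAAAAA	9	2
terminal-3prime	TATTATAATATTTCACAT	9	2
mTERF	TGGCAGAGCCCGG	0	0
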