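mutation	primer_name	sequence
S12C	S12C-fwd	AACGTGCTTCTTGTTTCGAATGGTTCGGT
S12C	S12C-rev	ACCGAACCATTCGAAACAAGAAGCACGTT
A270C	A270C-fwd	TGCTGGATTATTTGTGTGAAAACTCAGACGT
A270C	A270C-rev	ACGTCTGAGTTTTCACACAAATAATCCAGC
S127C	S127C-fwd	TGGTCCACACTGGCCTGTCAATTCAAATCA
S127C	S127C-rev	TGATTTGAATTGACAGGCCAGTGTGGACCA
A165C	A165C-fwd	ATGGCATCCGCGACTGTGGTGCAACAA
A165C	A165C-rev	TTGTTGCACCACAGTCGCGGATGCCA
Y171C	Y171C-fwd	TGGCGCAACAACTCAATGTATCTTCGTTGA
Y171C	Y171C-rev	TCAACGAAGATACATTGAGTTGTTGCGCCA
L201C	L201C-fwd	ACTGACCCTTCTGATTGTATCGTCTACGAGAT
L201C	L201C-rev	ATCTCGTAGACGATACAATCAGAAGGGTCAGT
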