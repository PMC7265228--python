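gene	cluster	five_nonamer	five_spacer	five_heptamer	three_heptamer	three_spacer	three_nonamer
IGHD1-2	2	ggattttga	gggtgtgcgtgt	caccctg	cacagtg	actcaggccctg	acataaagt
IGHD1-3	3	ggattttga	gggtgtgcgtgt	caccgtg	cacagtg	actcaggccctg	acataaagt
IGHD1-4	4	ggattttga	gggtgtgcgtgt	caccgtg	cacagtg	actcaggccctg	acataaagt
IGHD2-2	2	gctttttgc	caagggctctac	tgcggtg	cacagtg	agacatggggca	gcaaaccct
IGHD2-3	3	gctttttgc	caagggctctac	tgcggtg	cacagtg	agacatggggca	gcaaaccct
IGHD2-4	4	gctttttgc	caagggctctac	tgcggtg	cacagtg	agacatggggca	gcaaaccct
IGHD3-3	3	ggtttctga	tgccggctgtgt	cacggtg	cacagtg	acactgtccagg	acagaaacc
IGHD3-4	4	ggtttctga	tgccggctgtgt	cacggtg	cacagtg	acactgtccagg	acagaaacc
IGHD7-3	3	ggtttttga	tgccggctgtgt	cacggtg	cacagtg	atactctctggg	acaaaaacc
IGHD7-4	4	ggtttttga	tgccggctgtgt	cacggtg	cacagtg	atactctctggg	acaaaaacc
IGHD8-2	2	ggtttctga	tgccggctgtgt	cacggtg	cacagtg	atactctctggg	acaaaaacc
IGHD5-2	2	ggtttctga	tgccggctgtgt	tgtggtg	cacagtg	atgctctcagtg	tcagaaacc
IGHD5-3	3	ggtttctga	tgccggctgtgt	tgtggtg	cacagtg	acgctctcagtg	tcagaaacc
IGHD5-4	4	ggtttctga	tgccggctgtgt	tgtggtg	cacagtg	acgctctcagtg	tcagaaacc
IGHD6-2	2	ggtttctga	tgccggctgtgt	cacggtg	cacagtg	acactctctggg	acaaaaacc
IGHD6-3	3	ggtttctga	tgccagctgtgt	cacggtg	cacagtg	acactctctggg	acaaaaacc
IGHD6-4	4	ggtttctga	tgccagctgtgt	cacggtg	cacagtg	acactctctggg	acaaaaacc
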