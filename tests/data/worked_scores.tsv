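gene_a	gene_b	max	bma
g1	g2	0.666667	0.666667
g1	g3	0.471679	0.471679
g1	g4	0.226024	0.226024
g1	g5	-0.000000	0.000000
g1	g6	-0.000000	0.000000
g1	g7	-0.000000	0.000000
g1	g8	0.226024	0.150683
g2	g3	0.471679	0.471679
g2	g4	0.226024	0.226024
g2	g5	-0.000000	0.000000
g2	g6	-0.000000	0.000000
g2	g7	-0.000000	0.000000
g2	g8	0.226024	0.150683
g3	g4	0.226024	0.226024
g3	g5	-0.000000	0.000000
g3	g6	-0.000000	0.000000
g3	g7	-0.000000	0.000000
g3	g8	0.226024	0.150683
g4	g5	-0.000000	0.000000
g4	g6	-0.000000	0.000000
g4	g7	-0.000000	0.000000
g4	g8	0.666667	0.444444
g5	g6	0.333333	0.333333
g5	g7	0.333333	0.333333
g5	g8	0.666667	0.444444
g6	g7	0.666667	0.666667
g6	g8	0.333333	0.222222
g7	g8	0.333333	0.222222
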