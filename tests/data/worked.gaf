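!gaf-version: 2.1
SYN	g1	g1p		GO:0000008	SYN_REF:0000001	IDA		C	worked gene 1		gene	taxon:559292	20100301	SYN
SYN	g2	g2p		GO:0000007	SYN_REF:0000001	IDA		C	worked gene 2		gene	taxon:559292	20100301	SYN
SYN	g3	g3p		GO:0000005	SYN_REF:0000001	IDA		C	worked gene 3		gene	taxon:559292	20100301	SYN
SYN	g4	g4p		GO:0000006	SYN_REF:0000001	IDA		C	worked gene 4		gene	taxon:559292	20100301	SYN
SYN	g5	g5p		GO:0000012	SYN_REF:0000001	IDA		C	worked gene 5		gene	taxon:559292	20100301	SYN
SYN	g6	g6p		GO:0000011	SYN_REF:0000001	IDA		C	worked gene 6		gene	taxon:559292	20100301	SYN
SYN	g7	g7p		GO:0000009	SYN_REF:0000001	IDA		C	worked gene 7		gene	taxon:559292	20100301	SYN
SYN	g8	g8p		GO:0000010	SYN_REF:0000001	IDA		C	worked gene 8		gene	taxon:559292	20100301	SYN
SYN	g8	g8p		GO:0000006	SYN_REF:0000001	IDA		C	worked gene 8		gene	taxon:559292	20100301	SYN
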