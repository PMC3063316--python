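# name: SC35
# threshold: 2.383
# SYNTHETIC placeholder weights: the published SC35 nucleotide-frequency
# matrix is distributed with ESEfinder and is not reproduced here; only the
# motif width (8) and threshold (2.383) follow the published motif. Replace
# this file with the real matrix for production annotation.
A	C	G	T
-0.8	-0.8	-0.8	1.2
-0.8	-0.8	1.2	-0.8
-0.8	1.2	-0.8	-0.8
-0.8	1.2	-0.8	-0.8
1.2	-0.8	-0.8	-0.8
-0.8	1.2	-0.8	-0.8
1.2	-0.8	-0.8	-0.8
-0.8	1.2	-0.8	-0.8
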