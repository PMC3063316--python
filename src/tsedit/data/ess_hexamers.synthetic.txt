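# SYNTHETIC subset of a FAS-hex-3 style exonic-splicing-silencer hexamer
# set.  The full published list is external; this file carries the four
# hexamers whose gain/loss the pipeline's worked examples exercise.
# Replace with the complete FAS-hex-3 list for production annotation.
GGGAGG
TAGGTA
TTAGGT
CTTAGG
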