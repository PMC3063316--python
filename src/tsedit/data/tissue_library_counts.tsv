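tissue	n_libraries	n_sequences
adipose tissue	5	68
adrenal gland	5	120
ascites	1	76
bladder	2	22
blood	10	139
bone	12	385
bone marrow	10	101
brain	52	3090
cervix	6	127
connective tissue	6	161
ear	1	17
esophagus	3	23
eye	22	583
heart	2	25
intestine	20	366
kidney	13	336
larynx	3	4
liver	10	473
lung	16	438
lymph	19	429
lymph node	2	187
mammary gland	11	271
mouth	7	148
muscle	6	233
nerve	23	651
ovary	8	169
pancreas	10	707
parathyroid	1	62
pharynx	1	41
pituitary gland	3	47
placenta	9	566
prostate	11	265
salivary gland	3	62
skin	23	488
spleen	2	271
stomach	4	78
testis	6	386
thymus	1	520
thyroid	4	79
tonsil	4	292
trachea	1	200
uterus	18	506
vascular	3	13
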