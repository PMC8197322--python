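#source: synthetic-demo (truncated to 15 targets/miRNA)
#version: 1
mirna	gene
hsa-miR-1274A	GENE0317
hsa-miR-1274A	GENE1157
hsa-miR-1274A	GENE1495
hsa-miR-1274A	GENE2214
hsa-miR-1274A	GENE2605
hsa-miR-1274A	GENE3188
hsa-miR-1274A	GENE3354
hsa-miR-1274A	GENE3818
hsa-miR-1274B	GENE0921
hsa-miR-1274B	GENE3439
hsa-miR-1274B	GENE3554
hsa-miR-130b-3p	ESR1
hsa-miR-130b-3p	GENE0046
hsa-miR-130b-3p	GENE0076
hsa-miR-130b-3p	GENE0083
hsa-miR-130b-3p	GENE0085
hsa-miR-130b-3p	GENE0095
hsa-miR-130b-3p	GENE0125
hsa-miR-130b-3p	GENE0128
hsa-miR-130b-3p	GENE0133
hsa-miR-130b-3p	GENE0172
hsa-miR-130b-3p	GENE0179
hsa-miR-130b-3p	GENE0190
hsa-miR-130b-3p	GENE0210
hsa-miR-130b-3p	GENE0212
hsa-miR-130b-3p	GENE0213
hsa-miR-140-3p	ESR2
hsa-miR-140-3p	GENE0032
hsa-miR-140-3p	GENE0038
hsa-miR-140-3p	GENE0062
hsa-miR-140-3p	GENE0188
hsa-miR-140-3p	GENE0254
hsa-miR-140-3p	GENE0305
hsa-miR-140-3p	GENE0344
hsa-miR-140-3p	GENE0360
hsa-miR-140-3p	GENE0361
hsa-miR-140-3p	GENE0385
hsa-miR-140-3p	GENE0499
hsa-miR-140-3p	GENE0503
hsa-miR-140-3p	GENE0552
hsa-miR-140-3p	GENE0569
hsa-miR-146b-5p	AGO1
hsa-miR-146b-5p	GENE0012
hsa-miR-146b-5p	GENE0040
hsa-miR-146b-5p	GENE0093
hsa-miR-146b-5p	GENE0095
hsa-miR-146b-5p	GENE0179
hsa-miR-146b-5p	GENE0195
hsa-miR-146b-5p	GENE0232
hsa-miR-146b-5p	GENE0234
hsa-miR-146b-5p	GENE0237
hsa-miR-146b-5p	GENE0272
hsa-miR-146b-5p	GENE0285
hsa-miR-146b-5p	GENE0320
hsa-miR-146b-5p	GENE0336
hsa-miR-146b-5p	GENE0337
hsa-miR-181a-5p	GENE0010
hsa-miR-181a-5p	GENE0013
hsa-miR-181a-5p	GENE0015
hsa-miR-181a-5p	GENE0018
hsa-miR-181a-5p	GENE0070
hsa-miR-181a-5p	GENE0095
hsa-miR-181a-5p	GENE0101
hsa-miR-181a-5p	GENE0102
hsa-miR-181a-5p	GENE0147
hsa-miR-181a-5p	GENE0179
hsa-miR-181a-5p	GENE0180
hsa-miR-181a-5p	GENE0212
hsa-miR-181a-5p	GENE0241
hsa-miR-181a-5p	GENE0271
hsa-miR-181a-5p	GENE0275
hsa-miR-185-5p	GENE0025
hsa-miR-185-5p	GENE0033
hsa-miR-185-5p	GENE0036
hsa-miR-185-5p	GENE0038
hsa-miR-185-5p	GENE0042
hsa-miR-185-5p	GENE0052
hsa-miR-185-5p	GENE0056
hsa-miR-185-5p	GENE0068
hsa-miR-185-5p	GENE0072
hsa-miR-185-5p	GENE0077
hsa-miR-185-5p	GENE0085
hsa-miR-185-5p	GENE0105
hsa-miR-185-5p	GENE0107
hsa-miR-185-5p	GENE0113
hsa-miR-185-5p	GENE0146
hsa-miR-210-3p	GENE0007
hsa-miR-210-3p	GENE0017
hsa-miR-210-3p	GENE0112
hsa-miR-210-3p	GENE0113
hsa-miR-210-3p	GENE0122
hsa-miR-210-3p	GENE0128
hsa-miR-210-3p	GENE0161
hsa-miR-210-3p	GENE0195
hsa-miR-210-3p	GENE0199
hsa-miR-210-3p	GENE0241
hsa-miR-210-3p	GENE0282
hsa-miR-210-3p	GENE0307
hsa-miR-210-3p	GENE0310
hsa-miR-210-3p	GENE0345
hsa-miR-210-3p	GENE0384
hsa-miR-24-3p	GENE0007
hsa-miR-24-3p	GENE0037
hsa-miR-24-3p	GENE0052
hsa-miR-24-3p	GENE0066
hsa-miR-24-3p	GENE0072
hsa-miR-24-3p	GENE0077
hsa-miR-24-3p	GENE0112
hsa-miR-24-3p	GENE0118
hsa-miR-24-3p	GENE0119
hsa-miR-24-3p	GENE0173
hsa-miR-24-3p	GENE0174
hsa-miR-24-3p	GENE0203
hsa-miR-24-3p	GENE0237
hsa-miR-24-3p	GENE0272
hsa-miR-24-3p	GENE0278
hsa-miR-26a-5p	AGO1
hsa-miR-26a-5p	ESR1
hsa-miR-26a-5p	GENE0002
hsa-miR-26a-5p	GENE0050
hsa-miR-26a-5p	GENE0072
hsa-miR-26a-5p	GENE0089
hsa-miR-26a-5p	GENE0095
hsa-miR-26a-5p	GENE0125
hsa-miR-26a-5p	GENE0130
hsa-miR-26a-5p	GENE0153
hsa-miR-26a-5p	GENE0182
hsa-miR-26a-5p	GENE0185
hsa-miR-26a-5p	GENE0189
hsa-miR-26a-5p	GENE0232
hsa-miR-26a-5p	GENE0265
hsa-miR-26b-5p	GENE0010
hsa-miR-26b-5p	GENE0029
hsa-miR-26b-5p	GENE0063
hsa-miR-26b-5p	GENE0067
hsa-miR-26b-5p	GENE0098
hsa-miR-26b-5p	GENE0101
hsa-miR-26b-5p	GENE0135
hsa-miR-26b-5p	GENE0146
hsa-miR-26b-5p	GENE0150
hsa-miR-26b-5p	GENE0156
hsa-miR-26b-5p	GENE0205
hsa-miR-26b-5p	GENE0213
hsa-miR-26b-5p	GENE0220
hsa-miR-26b-5p	GENE0248
hsa-miR-26b-5p	GENE0273
hsa-miR-27a-3p	APC
hsa-miR-27a-3p	EGFR
hsa-miR-27a-3p	FOXO1
hsa-miR-27a-3p	GENE0007
hsa-miR-27a-3p	GENE0017
hsa-miR-27a-3p	GENE0044
hsa-miR-27a-3p	GENE0057
hsa-miR-27a-3p	GENE0059
hsa-miR-27a-3p	GENE0061
hsa-miR-27a-3p	GENE0065
hsa-miR-27a-3p	GENE0108
hsa-miR-27a-3p	GENE0115
hsa-miR-27a-3p	GENE0120
hsa-miR-27a-3p	GENE0132
hsa-miR-27a-3p	GENE0134
hsa-miR-30a-5p	BNIP3L
hsa-miR-30a-5p	EGFR
hsa-miR-30a-5p	ESR2
hsa-miR-30a-5p	FOXO1
hsa-miR-30a-5p	GENE0001
hsa-miR-30a-5p	GENE0005
hsa-miR-30a-5p	GENE0009
hsa-miR-30a-5p	GENE0012
hsa-miR-30a-5p	GENE0025
hsa-miR-30a-5p	GENE0032
hsa-miR-30a-5p	GENE0035
hsa-miR-30a-5p	GENE0039
hsa-miR-30a-5p	GENE0044
hsa-miR-30a-5p	GENE0046
hsa-miR-30a-5p	GENE0047
hsa-miR-320a-3p	AGO1
hsa-miR-320a-3p	ESR2
hsa-miR-320a-3p	GENE0005
hsa-miR-320a-3p	GENE0041
hsa-miR-320a-3p	GENE0077
hsa-miR-320a-3p	GENE0108
hsa-miR-320a-3p	GENE0124
hsa-miR-320a-3p	GENE0125
hsa-miR-320a-3p	GENE0132
hsa-miR-320a-3p	GENE0145
hsa-miR-320a-3p	GENE0176
hsa-miR-320a-3p	GENE0210
hsa-miR-320a-3p	GENE0214
hsa-miR-320a-3p	GENE0256
hsa-miR-320a-3p	GENE0258
hsa-miR-324-3p	EGFR
hsa-miR-324-3p	GENE0029
hsa-miR-324-3p	GENE0040
hsa-miR-324-3p	GENE0042
hsa-miR-324-3p	GENE0061
hsa-miR-324-3p	GENE0067
hsa-miR-324-3p	GENE0070
hsa-miR-324-3p	GENE0077
hsa-miR-324-3p	GENE0079
hsa-miR-324-3p	GENE0092
hsa-miR-324-3p	GENE0096
hsa-miR-324-3p	GENE0117
hsa-miR-324-3p	GENE0137
hsa-miR-324-3p	GENE0164
hsa-miR-324-3p	GENE0175
hsa-miR-324-5p	GENE0015
hsa-miR-324-5p	GENE0038
hsa-miR-324-5p	GENE0044
hsa-miR-324-5p	GENE0061
hsa-miR-324-5p	GENE0082
hsa-miR-324-5p	GENE0114
hsa-miR-324-5p	GENE0116
hsa-miR-324-5p	GENE0117
hsa-miR-324-5p	GENE0123
hsa-miR-324-5p	GENE0127
hsa-miR-324-5p	GENE0145
hsa-miR-324-5p	GENE0166
hsa-miR-324-5p	GENE0192
hsa-miR-324-5p	GENE0194
hsa-miR-324-5p	GENE0196
hsa-miR-328-3p	AGO1
hsa-miR-328-3p	GENE0002
hsa-miR-328-3p	GENE0065
hsa-miR-328-3p	GENE0128
hsa-miR-328-3p	GENE0163
hsa-miR-328-3p	GENE0269
hsa-miR-328-3p	GENE0313
hsa-miR-328-3p	GENE0334
hsa-miR-328-3p	GENE0411
hsa-miR-328-3p	GENE0464
hsa-miR-328-3p	GENE0470
hsa-miR-328-3p	GENE0472
hsa-miR-328-3p	GENE0475
hsa-miR-328-3p	GENE0498
hsa-miR-328-3p	GENE0528
hsa-miR-331-3p	AGO1
hsa-miR-331-3p	GENE0016
hsa-miR-331-3p	GENE0019
hsa-miR-331-3p	GENE0063
hsa-miR-331-3p	GENE0080
hsa-miR-331-3p	GENE0090
hsa-miR-331-3p	GENE0093
hsa-miR-331-3p	GENE0102
hsa-miR-331-3p	GENE0109
hsa-miR-331-3p	GENE0116
hsa-miR-331-3p	GENE0122
hsa-miR-331-3p	GENE0124
hsa-miR-331-3p	GENE0125
hsa-miR-331-3p	GENE0129
hsa-miR-331-3p	GENE0134
hsa-miR-345-5p	GENE0090
hsa-miR-345-5p	GENE0167
hsa-miR-345-5p	GENE0201
hsa-miR-345-5p	GENE0204
hsa-miR-345-5p	GENE0210
hsa-miR-345-5p	GENE0327
hsa-miR-345-5p	GENE0351
hsa-miR-345-5p	GENE0352
hsa-miR-345-5p	GENE0353
hsa-miR-345-5p	GENE0354
hsa-miR-345-5p	GENE0385
hsa-miR-345-5p	GENE0446
hsa-miR-345-5p	GENE0455
hsa-miR-345-5p	GENE0534
hsa-miR-345-5p	GENE0540
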