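pathway	gene
Apoptosis	GENE0006
Apoptosis	GENE0030
Apoptosis	GENE0047
Apoptosis	GENE0058
Apoptosis	GENE0065
Apoptosis	GENE0076
Apoptosis	GENE0118
Apoptosis	GENE0120
Apoptosis	GENE0167
Apoptosis	GENE0197
Apoptosis	GENE0248
Apoptosis	GENE0253
Apoptosis	GENE0254
Apoptosis	GENE0284
Apoptosis	GENE0288
Apoptosis	GENE0305
Apoptosis	GENE0350
Apoptosis	GENE0389
Apoptosis	GENE0397
Apoptosis	GENE0405
Cell cycle	GENE0015
Cell cycle	GENE0020
Cell cycle	GENE0022
Cell cycle	GENE0102
Cell cycle	GENE0131
Cell cycle	GENE0175
Cell cycle	GENE0181
Cell cycle	GENE0330
Cell cycle	GENE0346
Cell cycle	GENE0382
Cell cycle	GENE0410
Cell cycle	GENE0479
Cell cycle	GENE0493
Cell cycle	GENE0510
Cell cycle	GENE0521
Cell cycle	GENE0559
Cell cycle	GENE0575
Cell cycle	GENE0589
Cell cycle	GENE0613
Cell cycle	GENE0699
Cellular responses to stress	GENE0000
Cellular responses to stress	GENE0006
Cellular responses to stress	GENE0057
Cellular responses to stress	GENE0075
Cellular responses to stress	GENE0093
Cellular responses to stress	GENE0098
Cellular responses to stress	GENE0100
Cellular responses to stress	GENE0111
Cellular responses to stress	GENE0138
Cellular responses to stress	GENE0142
Cellular responses to stress	GENE0173
Cellular responses to stress	GENE0187
Cellular responses to stress	GENE0209
Cellular responses to stress	GENE0221
Cellular responses to stress	GENE0225
Cellular responses to stress	GENE0237
Cellular responses to stress	GENE0243
Cellular responses to stress	GENE0248
Cellular responses to stress	GENE0257
Cellular responses to stress	GENE0264
Direct p53 effectors	EGFR
Direct p53 effectors	GENE0045
Direct p53 effectors	GENE0055
Direct p53 effectors	GENE0062
Direct p53 effectors	GENE0088
Direct p53 effectors	GENE0112
Direct p53 effectors	GENE0122
Direct p53 effectors	GENE0139
Direct p53 effectors	GENE0183
Direct p53 effectors	GENE0216
Direct p53 effectors	GENE0234
Direct p53 effectors	GENE0289
Direct p53 effectors	GENE0378
Direct p53 effectors	GENE0379
Direct p53 effectors	GENE0409
Direct p53 effectors	GENE0418
Direct p53 effectors	GENE0439
Direct p53 effectors	GENE0445
Direct p53 effectors	GENE0446
Direct p53 effectors	GENE0466
Gene expression	FOXO1
Gene expression	GENE0001
Gene expression	GENE0003
Gene expression	GENE0004
Gene expression	GENE0006
Gene expression	GENE0010
Gene expression	GENE0016
Gene expression	GENE0023
Gene expression	GENE0025
Gene expression	GENE0028
Gene expression	GENE0030
Gene expression	GENE0033
Gene expression	GENE0034
Gene expression	GENE0036
Gene expression	GENE0038
Gene expression	GENE0041
Gene expression	GENE0043
Gene expression	GENE0044
Gene expression	GENE0048
Gene expression	GENE0049
Intrinsic pathway for apoptosis	ESR1
Intrinsic pathway for apoptosis	GENE0101
Intrinsic pathway for apoptosis	GENE0168
Intrinsic pathway for apoptosis	GENE0226
Intrinsic pathway for apoptosis	GENE0325
Intrinsic pathway for apoptosis	GENE0334
Intrinsic pathway for apoptosis	GENE0405
Intrinsic pathway for apoptosis	GENE0593
Intrinsic pathway for apoptosis	GENE0776
Intrinsic pathway for apoptosis	GENE1049
Intrinsic pathway for apoptosis	GENE1051
Intrinsic pathway for apoptosis	GENE1185
Intrinsic pathway for apoptosis	GENE1291
Intrinsic pathway for apoptosis	GENE1300
Intrinsic pathway for apoptosis	GENE1587
Intrinsic pathway for apoptosis	GENE1623
Intrinsic pathway for apoptosis	GENE1679
Intrinsic pathway for apoptosis	GENE2030
Intrinsic pathway for apoptosis	GENE2099
Intrinsic pathway for apoptosis	GENE2719
p53 pathway	GENE0242
p53 pathway	GENE0274
p53 pathway	GENE0282
p53 pathway	GENE0309
p53 pathway	GENE0363
p53 pathway	GENE0430
p53 pathway	GENE0468
p53 pathway	GENE0625
p53 pathway	GENE0743
p53 pathway	GENE0776
p53 pathway	GENE0825
p53 pathway	GENE0889
p53 pathway	GENE1093
p53 pathway	GENE1108
p53 pathway	GENE1131
p53 pathway	GENE1188
p53 pathway	GENE1264
p53 pathway	GENE1459
p53 pathway	GENE1646
p53 pathway	GENE1672
p53 signalling pathway	GENE0048
p53 signalling pathway	GENE0101
p53 signalling pathway	GENE0170
p53 signalling pathway	GENE0175
p53 signalling pathway	GENE0255
p53 signalling pathway	GENE0370
p53 signalling pathway	GENE0457
p53 signalling pathway	GENE0476
p53 signalling pathway	GENE0556
p53 signalling pathway	GENE0575
p53 signalling pathway	GENE0716
p53 signalling pathway	GENE0728
p53 signalling pathway	GENE0748
p53 signalling pathway	GENE0756
p53 signalling pathway	GENE0936
p53 signalling pathway	GENE0940
p53 signalling pathway	GENE0968
p53 signalling pathway	GENE0974
p53 signalling pathway	GENE1005
p53 signalling pathway	GENE1019
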