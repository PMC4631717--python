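target,n_actives,n_compounds
ACE,49,1846
ACHE,107,3999
ADA,39,966
ALR2,26,1021
AMPC,21,807
AR,79,2933
CDK2,72,2146
COMT,11,479
COX-1,25,936
COX-2,426,13715
DHFR,410,8777
EGFR,475,16471
ER agonist,67,2637
ER antagonist,39,1487
FGFR1,120,4670
FXA,146,5891
GART,40,919
GPB,52,2192
GR,78,3025
HIVPR,62,2100
HIVRT,43,1562
HMGR,35,1515
HSP90,37,1016
INHA,86,3352
MR,15,651
NA,49,1923
P38,454,9595
PARP,35,1386
PDE5,88,2066
PNP,50,1086
PPAR,85,3212
PR,27,1068
RXR,20,770
SAHH,33,1379
SRC,159,6478
THR,72,2528
TK,22,913
TRP,49,1713
VEGFR2,88,2994
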