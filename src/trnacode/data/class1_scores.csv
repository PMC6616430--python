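query,IleRS-IA,LeuRS-IA,MetRS-IA,ValRS-IA,ArgRS-ID,TrpRS-IC,TyrRS-IC,CysRS-IB,GluRS-IB,GlnRS-IB,LysRS-IE
IleRS-IA,NR,1449,846,1508,259,50,55,301,113,137,73
LeuRS-IA,1347,NR,780,1331,250,38,47,332,115,129,73
MetRS-IA,817,774,NR,805,349,52,35,435,156,126,159
ValRS-IA,1663,1322,854,NR,259,50,55,301,118,154,73
ArgRS-ID,261,274,370,266,NR,56,58,348,151,100,196
TrpRS-IC,34,38,68,34,52,NR,495,54,69,44,36
TyrRS-IC,33,29,33,25,41,485,NR,57,54,40,42
CysRS-IB,353,394,446,360,387,64,83,NR,258,293,220
GluRS-IB,59,86,139,61,121,65,67,167,NR,1203,331
GlnRS-IB,59,72,126,63,123,47,48,156,1538,NR,313
LysRS-IE,181,209,234,189,249,67,73,330,549,281,NR
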