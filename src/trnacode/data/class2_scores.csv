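query,SerRS-IIA,ThrRS-IIA,ProRS-IIA,GlyRS-IIA,HisRS-IIA,AspRS-IIB,AsnRS-IIB,LysRS-IIB,PheRS-IIC,pSerRS-IIC,AlaRS-IID,pyrroLysRS-IIC,GlyRS-IID
SerRS-IIA,NR,412,384,275,159,58,59,74,77,81,26,156,ND
ThrRS-IIA,412,NR,540,554,456,80,ND,75,77,69,ND,129,ND
ProRS-IIA,373,540,NR,495,378,63,ND,70,96,79,ND,127,ND
GlyRS-IIA,307,554,608,NR,392,63,ND,98,79,71,ND,141,ND
HisRS-IIA,149,456,339,393,NR,79,ND,181,104,83,17,123,ND
AspRS-IIB,68,80,71,57,156,NR,807,816,179,98,37,224,36
AsnRS-IIB,59,ND,ND,ND,ND,807,NR,778,98,81,33,216,ND
LysRS-IIB,69,75,75,66,180,815,778,NR,180,101,30,265,33
PheRS-IIC,72,77,69,60,64,107,98,106,NR,719,37,203,37
pSerRS-IIC,75,69,75,61,72,99,81,102,721,NR,32,321,32
AlaRS-IID,ND,ND,ND,ND,ND,36,33,ND,37,32,NR,37,597
pyrroLysRS-IIC,103,129,124,107,118,229,216,243,350,335,37,NR,37
GlyRS-IID,ND,ND,ND,ND,ND,36,ND,33,40,36,596,37,NR
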