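comp_id,parent,moiety
A,A,ribonucleotide
C,C,ribonucleotide
G,G,ribonucleotide
U,U,ribonucleotide
I,G,ribonucleotide
DA,DA,deoxyribonucleotide
DC,DC,deoxyribonucleotide
DG,DG,deoxyribonucleotide
DT,DT,deoxyribonucleotide
DU,DU,deoxyribonucleotide
DI,DG,deoxyribonucleotide
PSU,U,ribonucleotide
H2U,U,ribonucleotide
4SU,U,ribonucleotide
5MU,U,ribonucleotide
OMU,U,ribonucleotide
1MA,A,ribonucleotide
2MA,A,ribonucleotide
OMA,A,ribonucleotide
1MG,G,ribonucleotide
2MG,G,ribonucleotide
M2G,G,ribonucleotide
7MG,G,ribonucleotide
OMG,G,ribonucleotide
5MC,C,ribonucleotide
OMC,C,ribonucleotide
5CM,DC,deoxyribonucleotide
6OG,DG,deoxyribonucleotide
8OG,DG,deoxyribonucleotide
BRU,DU,deoxyribonucleotide
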