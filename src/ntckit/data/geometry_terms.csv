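term_name,term_type,atom1,atom2,atom3,applies_to
P-O5',bond,P,O5',,all
P-OP1,bond,P,OP1,,all
P-OP2,bond,P,OP2,,all
O5'-C5',bond,O5',C5',,all
C5'-C4',bond,C5',C4',,all
C4'-C3',bond,C4',C3',,all
C3'-O3',bond,C3',O3',,all
C4'-O4',bond,C4',O4',,all
O4'-C1',bond,O4',C1',,all
C1'-C2',bond,C1',C2',,all
C2'-C3',bond,C2',C3',,all
OP1-P-O5',angle,OP1,P,O5',all
OP2-P-O5',angle,OP2,P,O5',all
P-O5'-C5',angle,P,O5',C5',all
O5'-C5'-C4',angle,O5',C5',C4',all
C5'-C4'-C3',angle,C5',C4',C3',all
C4'-C3'-O3',angle,C4',C3',O3',all
C5'-C4'-O4',angle,C5',C4',O4',all
C4'-O4'-C1',angle,C4',O4',C1',all
O4'-C1'-C2',angle,O4',C1',C2',all
C2'-O2',bond,C2',O2',,ribose
C1'-C2'-O2',angle,C1',C2',O2',ribose
C1'-N9,bond,C1',N9,,purine
N9-C4,bond,N9,C4,,purine
C4-C5,bond,C4,C5,,purine
C5-N7,bond,C5,N7,,purine
N7-C8,bond,N7,C8,,purine
C8-N9,bond,C8,N9,,purine
C4-N3,bond,C4,N3,,purine
N3-C2,bond,N3,C2,,purine
C2-N1,bond,C2,N1,,purine
N1-C6,bond,N1,C6,,purine
C6-C5,bond,C6,C5,,purine
O4'-C1'-N9,angle,O4',C1',N9,purine
C1'-N9-C4,angle,C1',N9,C4,purine
N9-C4-C5,angle,N9,C4,C5,purine
C4-C5-N7,angle,C4,C5,N7,purine
C5-N7-C8,angle,C5,N7,C8,purine
N7-C8-N9,angle,N7,C8,N9,purine
C5-C4-N3,angle,C5,C4,N3,purine
C4-N3-C2,angle,C4,N3,C2,purine
N3-C2-N1,angle,N3,C2,N1,purine
C2-N1-C6,angle,C2,N1,C6,purine
N1-C6-C5,angle,N1,C6,C5,purine
C6-N6,bond,C6,N6,,A
N1-C6-N6,angle,N1,C6,N6,A
C6-O6,bond,C6,O6,,G
C2-N2,bond,C2,N2,,G
N1-C6-O6,angle,N1,C6,O6,G
N3-C2-N2,angle,N3,C2,N2,G
C1'-N1,bond,C1',N1,,pyrimidine
N1-C2,bond,N1,C2,,pyrimidine
C2-N3,bond,C2,N3,,pyrimidine
N3-C4,bond,N3,C4,,pyrimidine
C5-C4,bond,C5,C4,,pyrimidine
C5-C6,bond,C5,C6,,pyrimidine
C6-N1,bond,C6,N1,,pyrimidine
C2-O2,bond,C2,O2,,pyrimidine
O4'-C1'-N1,angle,O4',C1',N1,pyrimidine
C1'-N1-C2,angle,C1',N1,C2,pyrimidine
N1-C2-N3,angle,N1,C2,N3,pyrimidine
C2-N3-C4,angle,C2,N3,C4,pyrimidine
N3-C4-C5,angle,N3,C4,C5,pyrimidine
C4-C5-C6,angle,C4,C5,C6,pyrimidine
C5-C6-N1,angle,C5,C6,N1,pyrimidine
N1-C2-O2,angle,N1,C2,O2,pyrimidine
C4-O4,bond,C4,O4,,U
N3-C4-O4,angle,N3,C4,O4,U
C4-N4,bond,C4,N4,,C
N3-C4-N4,angle,N3,C4,N4,C
C4-O4T,bond,C4,O4,,T
N3-C4-O4T,angle,N3,C4,O4,T
C5-C7,bond,C5,C7,,T
C4-C5-C7,angle,C4,C5,C7,T
O3'-P,bond,p:O3',P,,linkage
C3'-O3'-P,angle,p:C3',p:O3',P,linkage
O3'-P-O5',angle,p:O3',P,O5',linkage
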