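kind,name,value
bond,O3'-P,1.607
bond,P-O5',1.593
bond,P-OP1,1.485
bond,P-OP2,1.485
bond,O5'-C5',1.440
bond,C5'-C4',1.510
bond,C4'-C3',1.524
bond,C3'-O3',1.423
bond,C4'-O4',1.453
bond,O4'-C1',1.415
bond,C1'-C2',1.528
bond,C2'-O2',1.413
bond,C1'-N,1.470
bond,N9-C4,1.374
bond,C4-C5,1.383
bond,C5-N7,1.388
bond,N7-C8,1.311
bond,C4-N3,1.344
bond,N3-C2,1.331
bond,C2-N1,1.339
bond,N1-C6,1.392
bond,C6-N6,1.334
bond,C6-O6,1.237
bond,C2-N2,1.341
bond,N1-C2,1.397
bond,C2-N3,1.353
bond,C2-O2,1.240
bond,N3-C4,1.383
bond,C4-C5pyr,1.440
bond,C5-C6,1.340
bond,C4-O4,1.230
bond,C4-N4,1.335
bond,C5-C7,1.496
angle,C3'-O3'-P,119.7
angle,O3'-P-O5',104.0
angle,O3'-P-OP1,108.1
angle,O3'-P-OP2,108.3
angle,P-O5'-C5',120.9
angle,O5'-C5'-C4',110.2
angle,C5'-C4'-C3',115.5
angle,C4'-C3'-O3',110.6
angle,C5'-C4'-O4',109.2
angle,C4'-O4'-C1',109.9
angle,O4'-C1'-C2',106.4
angle,C1'-C2'-O2',110.0
angle,O4'-C1'-N,108.2
angle,C1'-N9-C4,126.5
angle,N9-C4-C5,105.7
angle,C4-C5-N7,110.7
angle,C5-N7-C8,103.9
angle,C5-C4-N3,126.8
angle,C4-N3-C2,111.0
angle,N3-C2-N1,128.6
angle,C2-N1-C6,118.6
angle,N1-C6-N6,118.9
angle,N1-C6-O6,119.9
angle,N3-C2-N2,119.9
angle,C1'-N1-C2,117.7
angle,N1-C2-N3,114.8
angle,N1-C2-O2,122.8
angle,C2-N3-C4,124.0
angle,N3-C4-C5pyr,115.0
angle,C4-C5-C6,118.0
angle,N3-C4-O4,120.0
angle,N3-C4-N4,118.0
angle,C4-C5-C7,119.0
torsion,ring_o4_offset,-119.0
torsion,ring_c1,-120.0
torsion,ring_c2,-20.0
torsion,ring_o2,-115.0
torsion,glyco_offset,122.0
torsion,op1_offset,115.0
torsion,op2_offset,-115.0
torsion,seed_gamma,54.0
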