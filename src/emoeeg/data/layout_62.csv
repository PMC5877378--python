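name,x,y
Fp1,-0.3475,0.9907
Fpz,0.0013,1.0124
Fp2,0.3485,0.9905
AF7,-0.6723,0.8406
AF3,-0.3383,0.7713
AFz,0.0021,0.7369
AF4,0.3507,0.7633
AF8,0.6725,0.8404
F7,-0.9311,0.5628
F5,-0.6960,0.5186
F3,-0.4582,0.4844
F1,-0.2239,0.4636
Fz,0.0025,0.4596
F2,0.2401,0.4686
F4,0.4716,0.4940
F6,0.7078,0.5193
F8,0.9303,0.5657
FT7,-1.0697,0.1870
FC5,-0.7872,0.1901
FC3,-0.5113,0.1930
FC1,-0.2489,0.1901
FCz,0.0026,0.1907
FC2,0.2566,0.1950
FC4,0.5208,0.1983
FC6,0.7911,0.1983
FT8,1.0673,0.2011
T7,-1.0503,-0.1999
C5,-0.7699,-0.1320
C3,-0.5020,-0.0893
C1,-0.2429,-0.0671
Cz,0.0025,-0.0581
C2,0.2556,-0.0653
C4,0.5146,-0.0836
C6,0.7789,-0.1192
T8,1.0534,-0.1860
TP9,-1.1241,-0.6107
TP7,-0.9198,-0.4990
CP5,-0.6852,-0.4008
CP3,-0.4494,-0.3324
CP1,-0.2197,-0.2926
CPz,0.0023,-0.2828
CP2,0.2374,-0.2911
CP4,0.4652,-0.3257
CP6,0.6986,-0.3865
TP8,0.9240,-0.4919
TP10,1.1220,-0.6125
P7,-0.7129,-0.7230
P5,-0.5468,-0.6201
P3,-0.3690,-0.5485
P1,-0.1807,-0.5085
Pz,0.0020,-0.4942
P2,0.1985,-0.5005
P4,0.3827,-0.5400
P6,0.5524,-0.6177
P8,0.7181,-0.7182
PO7,-0.4823,-0.8578
PO3,-0.2681,-0.7406
PO4,0.2713,-0.7440
PO8,0.4877,-0.8553
O1,-0.2408,-0.9207
Oz,0.0009,-0.9192
O2,0.2447,-0.9198
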