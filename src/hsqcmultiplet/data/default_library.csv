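# hsqcmultiplet-library v1
metabolite,moiety,delta_h,delta_c,couplings
lactate,C2,4.11,69.3,C1:54.9;C3:37.1
lactate,C3,1.32,20.8,C2:37.1
alanine,C2,3.77,51.2,C1:54.2;C3:35.1
alanine,C3,1.47,16.8,C2:35.1
glutamate,C2,3.75,55.5,C1:53.4;C3:34.5
glutamate,C3a,2.04,27.7,C2:34.5;C4:34.3
glutamate,C3b,2.12,27.7,C2:34.5;C4:34.3
glutamate,C4,2.34,34.2,C3:34.3;C5:51.6
aspartate,C2,3.89,52.7,C1:53.8;C3:36.4
aspartate,C3a,2.66,37.4,C2:36.4;C4:51.2
aspartate,C3b,2.80,37.4,C2:36.4;C4:51.2
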