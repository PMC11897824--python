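# Hand-held four-site StO2 survey of the kidney later subjected to the pump
# step-down (simulated arterial thrombosis). The negative-time round was
# acquired during surgical benching, before perfusion started.
time_s,site,sto2
-3000,hilum,0
-3000,superior,0
-3000,lateral,0.089
-3000,inferior,0.745
3600,hilum,0.992
3600,superior,0.934
3600,lateral,0.947
3600,inferior,0.942
6600,hilum,0.707
6600,superior,0.286
6600,lateral,0.831
6600,inferior,0.790
8400,hilum,0.971
8400,superior,0.937
8400,lateral,0.971
8400,inferior,0.887
10800,hilum,0.687
10800,superior,0.919
10800,lateral,0.749
10800,inferior,0.903
12900,hilum,0.806
12900,superior,0.851
12900,lateral,0.913
12900,inferior,0.904
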