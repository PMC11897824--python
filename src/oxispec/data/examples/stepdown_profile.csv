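# StO2 fitted at the superior margin while the perfusion pump flow was stepped
# from 100% to 0% of full flow in 25% decrements (simulated arterial thrombosis).
flow_pct,sto2
100,0.859
75,0.819
50,0.786
25,0.593
0,0.595
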