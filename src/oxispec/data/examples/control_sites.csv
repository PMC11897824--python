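# Hand-held four-site StO2 survey of the control kidney for the simulated
# rejection experiment (placebo added between the second and third rounds).
# Times are seconds from perfusion start.
time_s,site,sto2
3600,hilum,0.873
3600,superior,0.834
3600,lateral,0.991
3600,inferior,0.923
5700,hilum,0.895
5700,superior,0.960
5700,lateral,0.950
5700,inferior,0.929
7200,hilum,0.895
7200,superior,0.949
7200,lateral,0.978
7200,inferior,0.941
9300,hilum,0.917
9300,superior,0.885
9300,lateral,0.962
9300,inferior,0.873
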