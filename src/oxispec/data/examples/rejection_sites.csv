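# Hand-held four-site StO2 survey of an ex vivo normothermically perfused human
# kidney subjected to a simulated antibody-mediated rejection intervention.
# Times are seconds from perfusion start; the intervention falls between the
# second and third survey rounds.
time_s,site,sto2
1800,hilum,0.834
1800,superior,0.804
1800,lateral,0.635
1800,inferior,0.426
6000,hilum,0.464
6000,superior,0.743
6000,lateral,0.759
6000,inferior,0.746
7500,hilum,0.474
7500,superior,0.750
7500,lateral,0.445
7500,inferior,0.436
9600,hilum,0.366
9600,superior,0.688
9600,lateral,0.599
9600,inferior,0.506
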