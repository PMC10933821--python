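label,de_exp,de_lecc_botec,de_lecc_leoc
1-H,3.1,0.3,1.2
1-Me,-4.5,-6.1,-5.7
1-OMe,-0.8,-1.4,0.5
1-NMe2,-5.3,-12.6,-4.4
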