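system,term_type,group_a,group_b,reg
1-H,V_xc,A,B,0.05
1-H,V_xc,C,D,0.07
1-H,V_xc,E,F,0.10
1-H,V_cl,A,B,0.67
1-H,V_cl,C,D,-0.05
1-H,V_cl,E,F,0.02
1-Me,V_xc,A,B,0.21
1-Me,V_xc,C,D,0.33
1-Me,V_xc,E,F,0.06
1-Me,V_cl,A,B,2.07
1-Me,V_cl,C,D,0.28
1-Me,V_cl,E,F,0.30
1-OMe,V_xc,A,B,0.06
1-OMe,V_xc,C,D,0.19
1-OMe,V_xc,E,F,0.18
1-OMe,V_cl,A,B,1.05
1-OMe,V_cl,C,D,0.28
1-OMe,V_cl,E,F,0.21
1-NMe2,V_xc,A,B,0.05
1-NMe2,V_xc,C,D,0.10
1-NMe2,V_xc,E,F,0.27
1-NMe2,V_cl,A,B,3.28
1-NMe2,V_cl,C,D,0.55
1-NMe2,V_cl,E,F,0.32
2-NO2,V_xc,A,B,0.22
2-NO2,V_xc,C,D,0.19
2-NO2,V_xc,E,F,0.31
2-NO2,V_cl,A,B,2.67
2-NO2,V_cl,C,D,0.00
2-NO2,V_cl,E,F,-0.12
2-CN,V_xc,A,B,0.21
2-CN,V_xc,C,D,0.18
2-CN,V_xc,E,F,0.27
2-CN,V_cl,A,B,2.64
2-CN,V_cl,C,D,0.03
2-CN,V_cl,E,F,-0.10
2-H,V_xc,A,B,0.19
2-H,V_xc,C,D,0.12
2-H,V_xc,E,F,0.22
2-H,V_cl,A,B,2.55
2-H,V_cl,C,D,-0.08
2-H,V_cl,E,F,-0.07
2-OMe,V_xc,A,B,0.18
2-OMe,V_xc,C,D,0.13
2-OMe,V_xc,E,F,0.17
2-OMe,V_cl,A,B,2.57
2-OMe,V_cl,C,D,-0.08
2-OMe,V_cl,E,F,-0.18
2-NMe2,V_xc,A,B,0.17
2-NMe2,V_xc,C,D,0.09
2-NMe2,V_xc,E,F,0.09
2-NMe2,V_cl,A,B,2.42
2-NMe2,V_cl,C,D,-0.11
2-NMe2,V_cl,E,F,-0.14
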