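system,term_type,atom_a,atom_b,reg,r
1-H,E_intra,n1,,-2.3,-0.96
1-H,V_cl,n1,o5,-1.4,-0.99
1-H,E_intra,c4,,-1.1,-0.98
1-H,V_xc,c4,o5,-0.8,-0.98
1-H,V_cl,c4,c22,-0.7,-0.92
1-H,E_intra,o5,,0.5,0.97
1-H,V_cl,o5,c22,0.7,0.82
1-H,V_cl,n1,c2,0.8,0.88
1-H,V_xc,n1,c4,1.0,0.96
1-H,V_cl,n1,c4,4.7,0.99
1-Me,V_cl,c4,c22,-2.5,-0.98
1-Me,V_cl,n1,o23,-2.5,-1.00
1-Me,V_cl,o5,o23,-2.3,-0.98
1-Me,E_intra,n1,,-2.0,-1.00
1-Me,V_cl,n1,o5,-1.2,-0.97
1-Me,V_cl,n1,c2,1.0,0.99
1-Me,V_cl,n1,c22,1.8,1.00
1-Me,V_cl,o5,c22,2.1,0.97
1-Me,V_cl,c4,o23,3.0,0.99
1-Me,V_cl,n1,c4,3.6,0.97
1-OMe,E_intra,n1,,-2.1,-0.98
1-OMe,V_cl,c4,c22,-1.2,-0.98
1-OMe,V_cl,n1,o5,-1.2,-0.99
1-OMe,E_intra,c4,,-1.1,-0.99
1-OMe,V_cl,o5,o23,-1.0,-0.97
1-OMe,V_xc,n1,c4,0.7,0.95
1-OMe,V_cl,n1,c2,0.8,0.92
1-OMe,V_cl,o5,c22,1.0,0.89
1-OMe,V_cl,c4,o23,1.5,0.99
1-OMe,V_cl,n1,c4,4.1,1.00
1-NMe2,V_cl,c4,c22,-3.2,-0.99
1-NMe2,V_cl,o5,n24,-2.6,-0.99
1-NMe2,V_cl,o5,o23,-2.5,-0.99
1-NMe2,V_cl,n1,o23,-1.9,-0.98
1-NMe2,E_intra,n1,,-1.6,-0.95
1-NMe2,V_cl,h13,o23,1.0,0.91
1-NMe2,V_cl,c4,n24,1.7,0.98
1-NMe2,V_cl,c4,o23,3.0,0.99
1-NMe2,V_cl,o5,c22,3.3,0.99
1-NMe2,V_cl,n1,c4,3.9,0.97
2-H,E_intra,n1,,-4.1,-0.99
2-H,V_cl,c3,c16,-2.2,-0.98
2-H,E_intra,c3,,-2.2,-1.00
2-H,V_cl,n1,o4,-1.9,-0.99
2-H,V_cl,o4,o17,-1.6,-1.00
2-H,V_cl,c3,o17,1.3,1.00
2-H,V_cl,n1,c6,1.4,0.97
2-H,V_cl,n1,c16,1.8,0.99
2-H,V_cl,o4,c16,2.5,1.00
2-H,V_cl,n1,c3,6.9,0.99
2-NO2,E_intra,n1,,-3.8,-0.99
2-NO2,V_cl,c3,c16,-2.3,-0.98
2-NO2,E_intra,c3,,-2.0,-1.00
2-NO2,V_cl,n1,o4,-1.8,-0.99
2-NO2,V_cl,o4,o17,-1.7,-1.00
2-NO2,V_cl,n1,c6,1.3,0.97
2-NO2,V_cl,c3,o17,1.3,1.00
2-NO2,V_cl,n1,c16,1.7,0.99
2-NO2,V_cl,o4,c16,2.7,1.00
2-NO2,V_cl,n1,c3,6.4,0.99
2-CN,E_intra,n1,,-3.8,-0.98
2-CN,V_cl,c3,c16,-2.3,-0.99
2-CN,E_intra,c3,,-2.0,-1.00
2-CN,V_cl,n1,o4,-1.8,-0.99
2-CN,V_cl,o4,o17,-1.6,-1.00
2-CN,V_cl,c3,o17,1.2,1.00
2-CN,V_cl,n1,c6,1.4,0.97
2-CN,V_cl,n1,c16,1.7,0.99
2-CN,V_cl,o4,c16,2.6,1.00
2-CN,V_cl,n1,c3,6.4,0.99
2-OMe,E_intra,n1,,-4.1,-0.99
2-OMe,V_cl,c3,c16,-2.3,-0.98
2-OMe,E_intra,c3,,-2.2,-1.00
2-OMe,V_cl,n1,o4,-1.9,-0.99
2-OMe,V_cl,o4,o17,-1.6,-1.00
2-OMe,V_cl,c3,o17,1.3,1.00
2-OMe,V_cl,n1,c6,1.4,0.97
2-OMe,V_cl,n1,c16,1.8,0.99
2-OMe,V_cl,o4,c16,2.6,1.00
2-OMe,V_cl,n1,c3,6.8,0.99
2-NMe2,E_intra,n1,,-4.2,-0.99
2-NMe2,E_intra,c3,,-2.3,-1.00
2-NMe2,V_cl,c3,c16,-2.1,-0.98
2-NMe2,V_cl,n1,o4,-1.9,-0.99
2-NMe2,V_cl,o4,o17,-1.5,-1.00
2-NMe2,V_cl,n1,c2,1.3,0.97
2-NMe2,V_cl,n1,c6,1.5,0.97
2-NMe2,V_cl,n1,c16,1.9,0.99
2-NMe2,V_cl,o4,c16,2.4,0.99
2-NMe2,V_cl,n1,c3,7.1,0.99
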