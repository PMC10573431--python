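adduct_id,protein,site,r1,r2,stereo,q_P,q_O,q_F,dist_P_O,dist_P_F,e_el_P_O_ref,e_el_P_F_ref,delta_e_el_ref
Ad1,BChE,Ser198,C2H5,N-(CH3)2,,2.240,-0.618,-0.748,1.686,2.753,-68.182,-50.540,17.642
Ad2,BChE,Ser198,C2H5,O-C2H5,,2.377,-0.599,-0.752,1.694,2.873,-69.797,-51.666,18.131
Ad3,BChE,Ser198,C2H5,C2H5,,2.306,-0.561,-0.739,1.691,3.742,-63.529,-37.818,25.711
Ad4,BChE,Ser198,C2H5,CH3,,2.334,-0.587,-0.726,1.688,3.073,-67.400,-45.790,21.610
Ad5,BChE,Ser198,CH(CH3)2,CH3,,2.327,-0.602,-0.721,1.687,3.222,-68.956,-43.241,25.715
Ad6,BChE,Ser198,CH2-CH(CH3)2,CH3,,2.284,-0.539,-0.745,1.691,3.684,-60.455,-38.355,22.100
Ad7,BChE,Ser198,nC4H9,CH3,,2.332,-0.549,-0.748,1.688,2.978,-62.983,-48.641,14.342
Ad8,BChE,Ser198,cC6H11,CH3,,2.362,-0.623,-0.703,1.692,3.763,-72.221,-36.643,35.577
Ad9,BChE,Ser198,C*H(CH3)-C(CH3)3,CH3,S,2.337,-0.647,-0.712,1.680,3.718,-74.739,-37.164,37.575
Ad10,BChE,Ser198,C*H(CH3)-C(CH3)3,CH3,R,2.299,-0.624,-0.701,1.687,3.918,-70.616,-34.158,36.458
Ad11,BChE,Ser198,C6H4-CH3,O-CH2-C6H4-OH,,2.406,-0.594,-0.753,1.684,2.823,-70.475,-53.293,17.181
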