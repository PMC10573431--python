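adduct_id,r1,r2,hydration,mean_dist_P_F
Ad1,C2H5,N-(CH3)2,2,2.91
Ad11,C6H4-CH3,O-CH2-C6H4-OH,3,2.96
Ad2,C2H5,O-C2H5,2,3.07
Ad7,nC4H9,CH3,3,3.18
Ad4,C2H5,CH3,3,3.32
Ad5,CH(CH3)2,CH3,3,3.37
Ad6,CH2-CH(CH3)2,CH3,3,3.43
Ad10,C*H(CH3)-C(CH3)3,CH3,3,3.50
Ad3,C2H5,C2H5,3,3.52
Ad8,cC6H11,CH3,4,3.52
Ad9,C*H(CH3)-C(CH3)3,CH3,4,3.56
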