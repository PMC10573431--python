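adduct_id,site,hydration,mean_dist_P_F,delta_e_el
Ad12,Tyr150,3,3.805,39.698
Ad13,Tyr150,3,3.920,39.659
Ad14,Tyr150,4,4.879,43.281
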