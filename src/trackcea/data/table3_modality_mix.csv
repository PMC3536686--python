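name,stage,w_oae,w_aabr,w_both,p_stage2_aabr,printed_mean_eur
c_1st_test_2stages,1,0.952,0.048,0.0,0.0766,42.22
c_2nd_test_1stage_ENT,2,0.747,0.149,0.104,0.0,38.99
c_3rd_test_1stage_ENT,3,0.403,0.388,0.209,0.0,43.39
c_test_PA,4,0.0,1.0,0.0,0.0,91.83
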