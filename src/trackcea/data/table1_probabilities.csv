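name,description,mean,ci_low,ci_high,source
p_Ltfu1_t,Probability of loss to follow-up before the initial hearing screening test with tracking,0.045,0.043,0.047,pilot project
p_Ltfu1_nt,Probability of loss to follow-up before the initial hearing screening test without tracking,0.053,0.051,0.055,pilot project
p_Ltfu2_t,Probability of loss to follow-up before 2nd test with tracking,0.07,0.057,0.084,state-wide programme 2010
p_Ltfu2_nt,Probability of loss to follow-up before 2nd test without tracking,0.51,0.497,0.524,state-wide programme 2010
p_Ltfu3_t,Probability of loss to follow-up before 3rd test with tracking,0.08,0.048,0.117,state-wide programme 2010
p_Ltfu3_nt,Probability of loss to follow-up before 3rd test without tracking,0.29,0.256,0.325,state-wide programme 2010
p_Ltfu4_t,Probability of loss to follow-up before 4th test with tracking,0.07,0.027,0.133,state-wide programme 2010
p_Ltfu4_nt,Probability of loss to follow-up before 4th test without tracking,0.18,0.133,0.239,state-wide programme 2010
p_fail_1st_test,Probability of failing the initial hearing screening test bilaterally,0.006,0.005,0.007,pilot project
p_fail_2nd_test,Probability of failing the 2nd test bilaterally,0.202,0.167,0.241,pilot project
p_fail_3rd_test,Probability of failing the 3rd test bilaterally,0.627,0.512,0.739,pilot project
p_fail_4th_test,Probability of failing the 4th test bilaterally,0.609,0.400,0.785,pilot project
p_diagnosis_after_2nd_test,Probability of diagnosis after 2nd test,0.11,0.073,0.159,state-wide programme 2010
p_diagnosis_after_3rd_test,Probability of diagnosis after 3rd test,0.36,0.261,0.460,state-wide programme 2010
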