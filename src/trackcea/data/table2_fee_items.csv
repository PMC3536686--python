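name,description,tariff_code,points,point_value_cents,printed_mean_eur,source
c_OAE_inpatient,OAE performed in hospital,1409,400,8.589704,34.36,DKG-NT
c_AABR_inpatient,AABR performed in hospital,1408,888,8.589704,76.28,DKG-NT
c_lumpsum_ENT,Lump sum for office-based ENT physicians,09210,680,3.5048,23.83,EBM
c_OAE_outpatient_ENT,OAE performed by office-based ENT physicians,09324,340,3.5048,11.92,EBM
c_AABR_outpatient_ENT,AABR performed by office-based ENT physicians,01706,705,3.5048,24.71,EBM
c_lumpsum_PA,Lump sum for office-based pediatric audiologists,20210,865,3.5048,30.32,EBM
c_AABR_outpatient_PA,AABR performed by office-based pediatric audiologists,20327,1535,3.5048,53.80,EBM
c_MEM_reflex_outpatient_PA,Impedance test of the middle ear by pediatric audiologists,20323,220,3.5048,7.71,EBM
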