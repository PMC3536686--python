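section,label,amount_eur
personnel,Nurse (0.75 position; tariff part E8),33876
personnel,Epidemiologist (0.5 position; tariff part E14),31759
non_personnel,Printing costs (flyer. data sheets),1500
non_personnel,Stamped addressed envelopes for hospitals and doctors' offices,1590
non_personnel,Telephone/fax,1000
non_personnel,Room,4200
non_personnel,Two desktop PCs,3000
non_personnel,One telephone (nationwide connection),100
non_personnel,Letters,1000
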