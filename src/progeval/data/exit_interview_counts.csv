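variable,level,satisfied,dissatisfied,is_reference
sex,male,23,11,1
sex,female,346,104,0
education,illiterate,220,32,1
education,read_write,63,16,0
education,primary,64,39,0
education,secondary,19,17,0
education,college,3,11,0
occupation,government,8,14,1
occupation,farmer,79,20,0
occupation,trader,27,13,0
occupation,housewife,243,60,0
occupation,daily_laborer,12,8,0
under_five_children,one,210,56,0
under_five_children,two,150,54,0
under_five_children,three,9,5,1
counseling,yes,338,91,0
counseling,no,31,24,1
hew_told_illness,yes,335,101,0
hew_told_illness,dont_know,10,5,0
hew_told_illness,no,24,9,1
prescribed_drugs,yes,325,84,0
prescribed_drugs,no,44,31,1
information_source,health_professional,302,80,0
information_source,family,27,11,0
information_source,neighbor,40,24,1
arrival_time,<60min,335,83,0
arrival_time,>=60min,34,32,1
waiting_time,<30min,351,101,0
waiting_time,>=30min,18,14,1
consultation_time,<15min,40,20,0
consultation_time,15-30min,319,90,0
consultation_time,>30min,10,5,1
appointment,yes,344,94,0
appointment,no,25,21,1
home_visit,yes,354,97,0
home_visit,no,15,18,1
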