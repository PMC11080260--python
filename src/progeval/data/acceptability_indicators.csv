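id,label,dimension,expected,observed,weight,score
ac01,Satisfied with convenience of working hours,acceptability,484,298,1.2,0.74
ac02,Satisfied with cleanliness of the health post,acceptability,484,255,1.1,0.58
ac03,Satisfied with appropriateness of the waiting area,acceptability,484,219,1.25,0.57
ac04,Satisfied with appropriateness of waiting time,acceptability,484,366,1.65,1.25
ac05,Satisfied with appropriateness of consultation time,acceptability,484,431,1.4,1.25
ac06,Satisfied with counseling service received,acceptability,484,391,2.15,1.74
ac07,Satisfied with explanation of the child's health status,acceptability,484,362,1.8,1.35
ac08,Satisfied with competence and knowledge of HEWs,acceptability,484,269,2.6,1.45
ac09,Satisfied with way of communication and respect from HEWs,acceptability,484,448,2,1.85
ac10,Satisfied with availability of drugs at the health post,acceptability,484,240,2.7,2.45
ac11,Satisfied with treatment given to the sick child,acceptability,484,389,2.45,1.96
ac12,Would recommend the service to family or friends,acceptability,484,341,1.25,0.88
ac13,Interested to return for the service next time,acceptability,484,409,1.45,1.22
ac14,Satisfied with the overall ICCM service,acceptability,484,374,2,1.54
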