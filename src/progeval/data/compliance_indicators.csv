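id,label,dimension,expected,observed,weight
co01,Sick children asked for chief complaint,compliance,42,42,2.4
co02,Sick children with weight measured,compliance,42,30,2.35
co03,Sick children with temperature measured,compliance,42,33,2.35
co04,Sick children checked for danger signs,compliance,42,32,2.7
co05,Children correctly assessed and classified in the last three months,compliance,230,230,4.5
co06,Pneumonia cases correctly treated,compliance,70,63,2.4
co07,Diarrhea cases correctly treated,compliance,82,72,2.4
co08,Malaria cases correctly treated,compliance,54,48,2.4
co09,Malnutrition cases correctly treated,compliance,34,27,2.4
co10,Caregivers counseled on food fluid and when to return,compliance,42,29,2.25
co11,Caregivers appointed for follow-up visit,compliance,230,208,2.25
co12,Mothers and children checked for HIV/AIDS status,compliance,230,171,1.75
co13,Sick children checked for anemia,compliance,230,153,1.75
co14,Sick children checked for immunization status,compliance,230,161,1.75
co15,Sick children checked for vitamin A supplementation status,compliance,218,179,1.75
co16,Sick children checked for de-worming status,compliance,119,93,1.75
co17,HPs supervised by higher health office in the last quarter,compliance,14,10,1.65
co18,HPs that sent reports during the reporting period,compliance,14,14,1.2
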