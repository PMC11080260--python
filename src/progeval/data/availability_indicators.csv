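id,label,dimension,expected,observed,weight
av01,HPs with HEW trained on ICCM/IMNCI,availability,14,11,3.4
av02,HPs with no stock-out of amoxicillin in the last six months,availability,14,14,2.5
av03,HPs with no stock-out of anti-malaria drugs in the last six months,availability,14,14,2.5
av04,HPs with no stock-out of zinc in the last six months,availability,14,11,2
av05,HPs with no stock-out of ORS in the last six months,availability,14,14,2.5
av06,HPs with no stock-out of albendazole in the last six months,availability,14,14,2.2
av07,HPs with no stock-out of vitamin A in the last six months,availability,14,14,2.2
av08,HPs with no stock-out of RUTF in the last six months,availability,14,6,2.5
av09,HPs with no stock-out of paracetamol in the last six months,availability,14,12,2.4
av10,HPs with MUAC tape measurement,availability,14,14,1.6
av11,HPs with functional thermometer,availability,14,14,1.6
av12,HPs with functional weight scale,availability,14,14,1.6
av13,HPs with ICCM guideline,availability,14,14,2.7
av14,HPs having ICCM registration book,availability,14,14,1.2
av15,HPs with monthly ICCM reporting format,availability,14,14,1
av16,HPs with functional ORT corner,availability,14,3,2
av17,HPs with functional timer,availability,14,0,1
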