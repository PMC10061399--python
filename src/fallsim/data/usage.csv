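row,column,value
total_person_years,uc,159169
total_person_years,rc,1710424
annual_average,uc,3979
annual_average,rc,42761
self_referred_annual,uc,47
self_referred_annual,rc,12793
proactive_annual,uc,1517
proactive_annual,rc,26928
falls_clinic_annual,rc,21131
horizon_years,value,40
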