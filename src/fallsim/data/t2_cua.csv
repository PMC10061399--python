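row,column,value
n_individuals,value,385192
allcause_public_cost,uc,10060099947
allcause_public_cost,rc,9936609337
allcause_public_cost,incremental,-123490610
fall_related_healthcare_cost,uc,663114733
fall_related_healthcare_cost,rc,560737568
fall_related_healthcare_cost,incremental,-102377165
intervention_public_cost,uc,33992444
intervention_public_cost,rc,430663194
intervention_public_cost,incremental,396670750
qaly,uc,2091707
qaly,rc,2110653
qaly,incremental,18946
productivity_value,uc,12828548949
productivity_value,rc,12867696042
productivity_value,incremental,39147094
intervention_toc,uc,1198057
intervention_toc,rc,42417182
intervention_toc,incremental,41219125
net_productivity_gain,incremental,-2072031
oop_expenditure,uc,2523459511
oop_expenditure,rc,2478690212
oop_expenditure,incremental,-44769299
co_payment,uc,8855861
co_payment,rc,75446429
co_payment,incremental,66590569
net_personal_finance_cost,incremental,21821270
informal_care_cost,uc,14884116295
informal_care_cost,rc,14744953134
informal_care_cost,incremental,-139163161
caregiver_toc,uc,356678
caregiver_toc,rc,51535375
caregiver_toc,incremental,51178696
net_informal_care_cost,incremental,-87984465
societal_gain_qaly_equivalent,incremental,1068
icer_societal_allcause_jackknife,value,14067
icer_societal_fallrelated_jackknife,value,15149
inmb_allcause,value,327260886
inmb_fallrelated,value,295215304
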