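row,column,value
n_cohort,value,5399
fair_health_innings,uc,4415
fair_health_innings,rc,4450
fair_wellbeing_innings,uc,4482
fair_wellbeing_innings,rc,4504
productive_ageing,uc,622
productive_ageing,rc,639
cpe,uc,553
cpe,rc,563
cpe_excl_copay,uc,550
cpe_excl_copay,rc,545
informal_burden,uc,1753
informal_burden,rc,1738
informal_burden_excl_toc,uc,1753
informal_burden_excl_toc,rc,1729
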