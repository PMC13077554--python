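outcome,outcome_type,qualified_events,qualified_n,unqualified_events,unqualified_n,qualified_mean,qualified_sd,unqualified_mean,unqualified_sd
adr,rate,145,270,34,240,,,,
adenoma_diminutive,rate,114,270,24,240,,,,
adenoma_small,rate,55,270,9,240,,,,
adenoma_large,rate,14,270,1,240,,,,
advanced_adenoma,rate,16,270,2,240,,,,
pdr,rate,242,270,96,240,,,,
polyp_diminutive,rate,222,270,83,240,,,,
polyp_small,rate,77,270,21,240,,,,
polyp_large,rate,19,270,3,240,,,,
mean_adenomas,mean,,270,,240,1.0,1.3,0.2,0.5
mean_polyps,mean,,270,,240,5.8,6.4,1.3,3.8
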