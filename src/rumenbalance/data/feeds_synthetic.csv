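feed,ap,ndf,sugars,starch
Beta vulgaris,6.0,14.0,65.0,0.0
Solanum tuberosum,5.0,6.0,2.0,74.0
Daucus carota,6.0,11.0,60.0,0.0
Pisum sativum,20.0,14.0,5.0,45.0
Grass silage,12.0,55.0,10.0,1.0
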