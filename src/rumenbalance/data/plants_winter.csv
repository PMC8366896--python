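species,n_sampled,twig_diameter,cp,ap,tnc1,lipids,lignin,cellulose,hemicellulose,ndf,dndf
Betula pendula,10,2.0,8.8,5.7,5.7,4.0,18.1,29.9,12.9,57.7,19.5
Betula pubescens,10,2.1,8.3,5.9,5.3,1.0,16.7,31.4,15.0,60.2,19.3
Calluna vulgaris,1,,7.8,6.1,10.6,2.2,12.5,23.3,8.3,42.1,24.3
Juniperus communis,3,1.7,6.8,5.4,8.5,3.1,10.8,30.2,3.6,42.6,19.7
Picea abies,11,2.5,8.2,7.4,15.8,2.0,9.8,21.2,10.6,40.1,20.8
Pinus sylvestris,11,2.3,9.2,8.4,10.1,4.1,9.5,25.6,9.7,43.1,21.3
Populus tremula,6,2.3,7.4,5.5,5.9,1.5,13.5,32.4,13.2,57.1,26.4
Quercus robur,9,2.1,6.6,4.3,7.3,0.2,18.3,30.5,13.5,59.2,21.3
Salix caprea,8,2.4,7.7,5.7,6.2,0.7,18.5,31.6,8.6,56.6,24.9
Sorbus aucuparia,11,2.7,6.5,5.1,5.6,0.9,13.9,27.7,12.8,52.2,18.3
Vaccinium myrtillus,4,,6.1,3.6,11.3,1.5,20.6,24.9,6.6,49.0,20.2
Vaccinium vitis-idaea,5,,6.5,3.3,13.9,2.5,19.8,21.9,4.5,44.7,21.5
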