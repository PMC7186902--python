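species,published_dry_ug_per_g,published_n,cup_mean_umol_per_g,cup_n,converted_published_umol_per_g,calibrated_cup_umol_per_g
P. pittieri,4474,10,6.582,71,34.42,67.13
P. auriculata,474,32,0.183,302,3.65,1.86
P. biflora,1542,25,2.188,303,11.86,22.32
P. lobata,115,8,0.000,4,0.88,0.00
P. menispermifolia,3460,7,5.936,25,26.62,60.55
P. oerstedii,1171,18,0.000,8,9.01,0.00
P. quadrangularis,1931,22,1.439,38,14.85,14.68
P. vitifolia,532,20,0.000,8,4.09,0.00
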