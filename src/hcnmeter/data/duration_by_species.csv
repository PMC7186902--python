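species,mean_min,sd_min,range_min,n
P. biflora,5.8,1.2,10.6,275
P. ambigua,6.2,2.8,42.5,314
P. pittieri,6.4,1.9,16.1,88
P. auriculata,6.7,1.8,12.7,329
P. costaricensis,6.9,1.5,5,23
P. arbelaezii,7.4,3.5,23,43
P. menispermifolia,7.4,4.6,22.1,31
P. quadrangularis,9.1,3.5,12,39
P. coriacea,39.6,21.5,80,39
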