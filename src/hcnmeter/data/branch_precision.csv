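species,data_curve_label,n,r_squared,rmse,curve_range,pct_error,p_value
P. auriculata,48 h alt leaf,6,0.99,0.019,0.7,2.8,0.0002
P. biflora,All data points,11,0.99,0.306,12,2.5,0.0001
P. biflora,14 h cut leaf,8,0.99,0.137,5,2.7,0.0001
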