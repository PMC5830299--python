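term,label,estimate,std_err,z_value,p_value
intercept,Intercept,0.455066,0.235548,1.9320,0.0617
sea_ice,sea_ice = no,-0.501833,0.322640,-1.5554,0.1190
ice_conc,ice_conc,0.058692,0.010952,5.3592,0.0001
ice_conc2,ice_conc^2,-0.000370,0.000098,-3.7946,0.0003
sqrt_d2ice,sqrt(d2ice),-0.206333,0.021916,-9.4149,0.0001
sea_ice:sqrt_d2ice,sqrt(d2ice)*(sea_ice = no),0.185093,0.036084,5.1296,0.0001
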