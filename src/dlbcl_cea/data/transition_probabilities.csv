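name,kind,lambda,k,value,range_low,range_high,time_unit,over_period_cycles,source
os_irchop,weibull,0.016,0.493,,,,years,,Wilson et al. 2021
ae_irchop,point,,,0.642,,,,1,Younes et al. 2019 (PHOENIX)
efs_irchop,weibull,0.181,1.350,,,,years,,Wilson et al. 2021
os_rchop,weibull,0.081,0.769,,,,years,,Wilson et al. 2021
ae_rchop,point,,,0.303,,,,1,Wilson et al. 2021
efs_rchop,weibull,0.187,0.884,,,,years,,Wilson et al. 2021
df_to_persistent,point,,,0.350,0.200,0.500,,20,Crump et al. 2017
os_gdp,weibull,0.0638,0.708,,,,years,,Crump et al. 2014
salvage_response,point,,,0.3755,0.300,0.451,,1,Crump et al. 2014 & 2017
pfs_gdp,weibull,0.152,0.603,,,,years,,Crump et al. 2014
sct_to_cart,point,,,0.201,,,,1,Di Blasi et al. 2021
sct_to_df,point,,,0.419,,,,1,Crump et al. 2017
sct_to_relapse,point,,,0.500,,,,1,Crump et al. 2017
relapse_to_palliation,point,,,0.393,,,,1,Crump et al. 2017
os_cart,weibull,0.056,0.880,,,,years,,Sermer et al. 2020
pfs_cart,weibull,0.169,0.658,,,,years,,Sermer et al. 2020
cart_df_death,point,,,0.059,,,,4,Tomas et al. 2021
cart_df_relapse,weibull,0.150,0.876,,,,years,,Di Blasi et al. 2021
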