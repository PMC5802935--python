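source,target,process,orientation,best,low,high,units,significance
External,forest,GPP,vertical,3233,3119,3347,Gg C yr-1,unset
External,forest,precipitation,vertical,6.2,4.1,8.3,Gg C yr-1,unset
forest,forest,accumulation,internal,968,873,1063,Gg C yr-1,unset
forest,External,respiration,vertical,2238,2176,2301,Gg C yr-1,unset
forest,surface_waters,DIC_runoff,lateral,10,4,17,Gg C yr-1,unset
forest,surface_waters,DOC_runoff,lateral,14,5,23,Gg C yr-1,unset
forest,surface_waters,litter,lateral,2.3,1.2,3.5,Gg C yr-1,unset
External,wetland,GPP,vertical,878,836,919,Gg C yr-1,unset
External,wetland,precipitation,vertical,3.2,2.1,4.3,Gg C yr-1,unset
wetland,wetland,accumulation,internal,89,27,152,Gg C yr-1,unset
wetland,External,respiration,vertical,754,679,829,Gg C yr-1,unset
wetland,External,CH4,vertical,13,1,25,Gg C yr-1,unset
wetland,surface_waters,DIC_runoff,lateral,1.0,-2.2,4.2,Gg C yr-1,unset
wetland,surface_waters,DOC_runoff,lateral,20,4,35,Gg C yr-1,unset
wetland,surface_waters,litter,lateral,0.7,0.3,1.0,Gg C yr-1,unset
External,surface_waters,precipitation,vertical,1.5,1.0,2.0,Gg C yr-1,unset
surface_waters,surface_waters,accumulation,internal,-15,-40,9,Gg C yr-1,unset
surface_waters,surface_waters,sediment,internal,17,8,26,Gg C yr-1,unset
surface_waters,External,CO2_evasion,vertical,28,22,34,Gg C yr-1,unset
surface_waters,External,CH4,vertical,2.2,1.1,3.3,Gg C yr-1,unset
surface_waters,External,runoff_export,lateral,34,23,45,Gg C yr-1,unset
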