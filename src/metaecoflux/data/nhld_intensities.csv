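# NHLD flux intensities and geometry.
# areal values in g C m-2 yr-1, lineal in g C m-1 of shoreline yr-1,
# areas in m2, lengths in m.
# Compartment areas are back-derived from (total flux) / (local intensity)
# pairs of the regional budget: forest from GPP 3233e9/936, wetland from
# GPP 878e9/490, surface waters from CO2 evasion 28e9/33.
compartment,process,basis,value,units
all,precipitation,areal,1.8,g C m-2 yr-1
forest,GPP,areal,936,g C m-2 yr-1
forest,respiration,areal,648,g C m-2 yr-1
forest,DIC_runoff,areal,3.0,g C m-2 yr-1
forest,DOC_runoff,areal,4.0,g C m-2 yr-1
wetland,GPP,areal,490,g C m-2 yr-1
wetland,respiration,areal,421,g C m-2 yr-1
wetland,CH4,areal,10,g C m-2 yr-1
wetland,DIC_runoff,areal,0.6,g C m-2 yr-1
wetland,DOC_runoff,areal,11,g C m-2 yr-1
surface_waters,CO2_evasion,areal,33,g C m-2 yr-1
surface_waters,CH4,areal,3,g C m-2 yr-1
surface_waters,sediment,areal,20,g C m-2 yr-1
forest,litter,lineal,300,g C m-1 yr-1
wetland,litter,lineal,200,g C m-1 yr-1
forest,,area,3454059829.06,m2
wetland,,area,1791836734.69,m2
surface_waters,,area,848484848.48,m2
forest,,length,7805000,m
wetland,,length,3469000,m
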