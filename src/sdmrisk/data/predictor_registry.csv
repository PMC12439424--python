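name,code,description,source,units
bio1,Bio1,Annual mean temperature,WorldClim,degC
bio2,Bio2,Mean diurnal range,WorldClim,degC
bio3,Bio3,Isothermality (Bio2/Bio7 x 100),WorldClim,degC
bio4,Bio4,Temperature seasonality (SD x 100),WorldClim,degC
bio5,Bio5,Max temperature of warmest month,WorldClim,degC
bio6,Bio6,Min temperature of coldest month,WorldClim,degC
bio7,Bio7,Temperature annual range,WorldClim,degC
bio8,Bio8,Mean temperature of wettest quarter,WorldClim,degC
bio9,Bio9,Mean temperature of driest quarter,WorldClim,degC
bio10,Bio10,Mean temperature of warmest quarter,WorldClim,degC
bio11,Bio11,Mean temperature of coldest quarter,WorldClim,degC
bio12,Bio12,Annual precipitation,WorldClim,mm
bio13,Bio13,Precipitation of wettest month,WorldClim,mm
bio14,Bio14,Precipitation of driest month,WorldClim,mm
bio15,Bio15,Precipitation seasonality,WorldClim,mm
bio16,Bio16,Precipitation of wettest quarter,WorldClim,mm
bio17,Bio17,Precipitation of driest quarter,WorldClim,mm
bio18,Bio18,Precipitation of warmest quarter,WorldClim,mm
bio19,Bio19,Precipitation of coldest quarter,WorldClim,mm
tmin,tmin,Minimum temperature,WorldClim,degC
tmax,tmax,Maximum temperature,WorldClim,degC
tavg,tavg,Average temperature,WorldClim,degC
prec,Prec,Precipitation,WorldClim,mm
wind,Wind,Wind speed,WorldClim,m s-1
vapr,Vapr,Water vapor pressure,WorldClim,kPa
cmi,CMI,Climatic moisture content,ENVIREM,-
srad,Srad,Solar radiation,WorldClim,kJ m-2 day-1
aridity,Aridity,Aridity index,ENVIREM,-
elev,Elev,Elevation,USGS,m
slope,SL,Slope,derived,%
aspect,AS,Aspect,derived,degree
ocd,OCD,Organic carbon density,SoilGrids,g/dm3
ocs,OCS,Soil organic carbon stock,SoilGrids,g/m2
bdod,BD,Bulk density,SoilGrids,cg/cm3
clay,Clay,Clay content,SoilGrids,g/kg
cfvo,CF,Coarse fragment,SoilGrids,cm3/dm3
sand,Sand,Sand,SoilGrids,g/kg
silt,Silt,Silt,SoilGrids,g/kg
cec,CEC,Cation exchange capacity,SoilGrids,mmol(c)/kg
nitrogen,N,Nitrogen,SoilGrids,cg/kg
soc,SOC,Soil organic carbon,SoilGrids,g/kg
phh2o,pH,pH water,SoilGrids,pH x 10
water10,Water10,Vol. water content at -10 kPa,SoilGrids,m3/m3
water33,Water33,Vol. water content at -33 kPa,SoilGrids,m3/m3
water1500,Water1500,Vol. water content at -1500 kPa,SoilGrids,m3/m3
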