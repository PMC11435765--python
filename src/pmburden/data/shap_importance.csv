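feature,mean_abs_shap
AOD,8.63
FMF,4.11
Temperature,2.05
DEM,1.56
Boundary layer height,1.21
Population,1.12
Slope,0.83
Relative humidity,0.59
Visibility,0.54
Wind speed,0.50
Precipitation,0.48
GDP,0.31
Surface pressure,0.18
Longitude,0.10
Latitude,0.08
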