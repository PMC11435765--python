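region,year,pm25
China,2007,47.41
China,2012,45.91
China,2017,35.95
China,2022,25.16
East,2007,56.84
East,2012,53.13
East,2017,42.01
East,2022,27.14
Northeast,2007,39.16
Northeast,2012,40.44
Northeast,2017,32.56
Northeast,2022,23.09
Centre,2007,67.09
Centre,2012,66.17
Centre,2017,47.08
Centre,2022,33.86
North,2007,43.67
North,2012,42.82
North,2017,33.05
North,2022,23.69
South,2007,44.97
South,2012,38.65
South,2017,31.59
South,2022,21.38
Northwest,2007,52.99
Northwest,2012,50.89
Northwest,2017,41.42
Northwest,2022,31.58
Southwest,2007,38.03
Southwest,2012,37.24
Southwest,2017,27.66
Southwest,2022,15.80
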