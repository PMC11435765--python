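region,year,gini
China,2007,0.026
China,2012,0.029
China,2017,0.028
China,2022,0.025
East,2007,0.028
East,2012,0.023
East,2017,0.019
East,2022,0.023
Northeast,2007,0.026
Northeast,2012,0.032
Northeast,2017,0.024
Northeast,2022,0.021
Centre,2007,0.024
Centre,2012,0.034
Centre,2017,0.036
Centre,2022,0.027
North,2007,0.033
North,2012,0.026
North,2017,0.031
North,2022,0.023
South,2007,0.018
South,2012,0.023
South,2017,0.016
South,2022,0.017
Northwest,2007,0.034
Northwest,2012,0.038
Northwest,2017,0.040
Northwest,2022,0.028
Southwest,2007,0.023
Southwest,2012,0.027
Southwest,2017,0.032
Southwest,2022,0.034
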