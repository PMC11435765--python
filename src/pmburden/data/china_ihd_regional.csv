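region,year,deaths,rate_per_1e5,ci_lower,ci_upper
China,2007,819287,61.96,720973,917601
China,2012,833170,61.53,733190,933150
China,2017,858290,61.75,755295,961285
China,2022,870138,61.66,765721,974555
East,2007,242901,57.28,213753,272049
East,2012,251996,56.60,221757,282236
East,2017,259496,57.01,228356,290635
East,2022,262026,55.15,230583,293469
Northeast,2007,67589,60.90,59478,75699
Northeast,2012,66902,61.37,58874,74930
Northeast,2017,68849,64.29,60587,77111
Northeast,2022,69885,66.47,61499,78272
Centre,2007,138096,57.47,121524,154667
Centre,2012,132607,56.04,116694,148520
Centre,2017,137384,55.17,120898,153870
Centre,2022,140963,54.86,124047,157878
North,2007,94431,79.04,83100,105763
North,2012,101042,81.82,88917,113167
North,2017,104176,81.47,91675,116677
North,2022,106734,80.08,93926,119542
South,2007,91838,54.31,80818,102859
South,2012,101191,55.54,89048,113334
South,2017,103699,53.67,91255,116142
South,2022,103260,51.58,90869,115651
Northwest,2007,58169,62.15,51188,65149
Northwest,2012,59607,61.73,52454,66760
Northwest,2017,61336,61.27,53976,68696
Northwest,2022,62653,61.22,55135,70172
Southwest,2007,126264,58.04,111112,141415
Southwest,2012,119826,56.72,105447,134205
Southwest,2017,123352,56.21,108549,138154
Southwest,2022,124618,55.81,109664,139572
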