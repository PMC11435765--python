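age_band,theta,theta_sd,alpha,mu,nu
25+,0.2969,0.01787,1.9,12,40.2
25-29,0.5070,0.02458,1.9,12,40.2
30-34,0.4762,0.02309,1.9,12,40.2
35-39,0.4455,0.02160,1.9,12,40.2
40-44,0.4148,0.02011,1.9,12,40.2
45-49,0.3841,0.01862,1.9,12,40.2
50-54,0.3533,0.01713,1.9,12,40.2
55-59,0.3226,0.01564,1.9,12,40.2
60-64,0.2919,0.01415,1.9,12,40.2
65-69,0.2612,0.01266,1.9,12,40.2
70-74,0.2304,0.01117,1.9,12,40.2
75-79,0.1997,0.00968,1.9,12,40.2
80+,0.1536,0.00740,1.9,12,40.2
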