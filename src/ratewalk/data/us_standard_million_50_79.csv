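stratum,weight
50-54,62716
55-59,48454
60-64,38793
65-69,34264
70-74,31773
75-79,26999
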