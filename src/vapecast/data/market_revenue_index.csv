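year,index_pct
2012,37
2013,44
2014,52
2015,62
2016,74
2017,87
2018,100
2019,110
2020,117
2021,129
2022,139
2023,148
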