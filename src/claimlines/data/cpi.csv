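year,deflator_to_2022
2010,1.4071
2011,1.3652
2012,1.3172
2013,1.2856
2014,1.2555
2015,1.2231
2016,1.1786
2017,1.1498
2018,1.1275
2019,1.0970
2020,1.0532
2021,1.0408
2022,1.0000
2023,0.9890
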