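indicator,sex,year,value
overweight_rate,boys,2000,9.6
overweight_rate,boys,2005,10.3
overweight_rate,boys,2010,12.0
overweight_rate,boys,2014,12.1
obesity_rate,boys,2000,5.4
obesity_rate,boys,2005,7.5
obesity_rate,boys,2010,8.8
obesity_rate,boys,2014,9.5
overweight_rate,girls,2000,7.0
overweight_rate,girls,2005,8.2
overweight_rate,girls,2010,9.1
overweight_rate,girls,2014,9.6
obesity_rate,girls,2000,3.4
obesity_rate,girls,2005,4.7
obesity_rate,girls,2010,5.2
obesity_rate,girls,2014,5.7
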