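indicator,sex,row,value
overweight_rate,boys,y2020,13.1
overweight_rate,boys,y2025,14.0
overweight_rate,boys,y2030,14.7
overweight_rate,boys,d2020_2000,3.5
overweight_rate,boys,d2030_2020,1.6
obesity_rate,boys,y2020,11.0
obesity_rate,boys,y2025,12.5
obesity_rate,boys,y2030,14.1
obesity_rate,boys,d2020_2000,5.6
obesity_rate,boys,d2030_2020,3.1
overweight_rate,girls,y2020,10.9
overweight_rate,girls,y2025,11.8
overweight_rate,girls,y2030,12.8
overweight_rate,girls,d2020_2000,3.8
overweight_rate,girls,d2030_2020,1.9
obesity_rate,girls,y2020,6.2
obesity_rate,girls,y2025,6.7
obesity_rate,girls,y2030,7.4
obesity_rate,girls,d2020_2000,2.8
obesity_rate,girls,d2030_2020,1.2
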