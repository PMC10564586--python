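indicator,sex,age,year,mean,sd
bmi,boys,3,2000,15.8,1.5
bmi,boys,3,2005,15.9,1.6
bmi,boys,3,2010,16.0,1.7
bmi,boys,3,2014,15.8,1.6
bmi,boys,3,2020,15.8,1.6
bmi,boys,4,2000,15.5,1.4
bmi,boys,4,2005,15.6,1.6
bmi,boys,4,2010,15.7,1.7
bmi,boys,4,2014,15.7,1.6
bmi,boys,4,2020,15.8,1.8
bmi,boys,5,2000,15.4,1.6
bmi,boys,5,2005,15.5,1.7
bmi,boys,5,2010,15.8,1.8
bmi,boys,5,2014,15.8,1.9
bmi,boys,5,2020,16.1,1.7
bmi,boys,6,2000,15.3,1.6
bmi,boys,6,2005,15.5,1.5
bmi,boys,6,2010,15.9,2.1
bmi,boys,6,2014,16.0,2.1
bmi,boys,6,2020,16.2,1.9
bmi,girls,3,2000,15.5,1.5
bmi,girls,3,2005,15.6,1.5
bmi,girls,3,2010,15.7,1.6
bmi,girls,3,2014,15.6,1.5
bmi,girls,3,2020,15.8,1.5
bmi,girls,4,2000,15.2,1.5
bmi,girls,4,2005,15.3,1.5
bmi,girls,4,2010,15.5,1.7
bmi,girls,4,2014,15.4,1.6
bmi,girls,4,2020,15.5,1.7
bmi,girls,5,2000,15.0,1.4
bmi,girls,5,2005,15.2,1.7
bmi,girls,5,2010,15.3,1.7
bmi,girls,5,2014,15.4,1.8
bmi,girls,5,2020,15.5,1.7
bmi,girls,6,2000,14.9,1.5
bmi,girls,6,2005,15.1,1.8
bmi,girls,6,2010,15.3,1.8
bmi,girls,6,2014,15.4,1.8
bmi,girls,6,2020,15.6,1.8
chest_circumference,boys,3,2000,51.7,2.9
chest_circumference,boys,3,2005,51.8,2.9
chest_circumference,boys,3,2010,52.5,3.0
chest_circumference,boys,3,2014,52.9,3.1
chest_circumference,boys,3,2020,52.3,3.1
chest_circumference,boys,4,2000,53.2,3.0
chest_circumference,boys,4,2005,53.2,3.2
chest_circumference,boys,4,2010,54.0,3.4
chest_circumference,boys,4,2014,54.5,3.4
chest_circumference,boys,4,2020,54.1,3.5
chest_circumference,boys,5,2000,54.8,3.4
chest_circumference,boys,5,2005,55.1,3.6
chest_circumference,boys,5,2010,56.0,3.9
chest_circumference,boys,5,2014,56.3,3.9
chest_circumference,boys,5,2020,56.3,3.7
chest_circumference,boys,6,2000,56.0,3.6
chest_circumference,boys,6,2005,56.6,4.2
chest_circumference,boys,6,2010,57.5,4.4
chest_circumference,boys,6,2014,58.2,4.5
chest_circumference,boys,6,2020,58.1,4.1
chest_circumference,girls,3,2000,50.5,3.1
chest_circumference,girls,3,2005,50.7,3.0
chest_circumference,girls,3,2010,51.3,3.0
chest_circumference,girls,3,2014,51.8,3.0
chest_circumference,girls,3,2020,51.2,3.2
chest_circumference,girls,4,2000,51.8,3.1
chest_circumference,girls,4,2005,51.8,3.1
chest_circumference,girls,4,2010,52.6,3.3
chest_circumference,girls,4,2014,53.1,3.2
chest_circumference,girls,4,2020,52.7,3.5
chest_circumference,girls,5,2000,53.2,3.3
chest_circumference,girls,5,2005,53.3,3.7
chest_circumference,girls,5,2010,54.2,3.6
chest_circumference,girls,5,2014,54.6,3.7
chest_circumference,girls,5,2020,54.6,3.7
chest_circumference,girls,6,2000,54.4,3.6
chest_circumference,girls,6,2005,54.7,4.0
chest_circumference,girls,6,2010,55.5,4.1
chest_circumference,girls,6,2014,56.2,3.9
chest_circumference,girls,6,2020,56.1,4.0
height,boys,3,2000,99.1,5.4
height,boys,3,2005,100.2,5.3
height,boys,3,2010,101.3,5.0
height,boys,3,2014,102.1,5.4
height,boys,3,2020,101.9,5.2
height,boys,4,2000,105.2,5.5
height,boys,4,2005,106.3,5.2
height,boys,4,2010,107.1,5.3
height,boys,4,2014,107.8,5.2
height,boys,4,2020,108.0,5.0
height,boys,5,2000,111.0,5.9
height,boys,5,2005,112.4,5.9
height,boys,5,2010,113.7,5.5
height,boys,5,2014,114.0,5.4
height,boys,5,2020,115.3,5.3
height,boys,6,2000,115.6,5.9
height,boys,6,2005,117.5,5.6
height,boys,6,2010,118.5,5.7
height,boys,6,2014,119.7,5.5
height,boys,6,2020,119.6,5.4
height,girls,3,2000,98.0,5.4
height,girls,3,2005,99.1,5.3
height,girls,3,2010,99.9,5.2
height,girls,3,2014,100.8,5.2
height,girls,3,2020,100.9,5.2
height,girls,4,2000,104.0,5.5
height,girls,4,2005,105.1,5.2
height,girls,4,2010,105.9,5.1
height,girls,4,2014,106.5,5.2
height,girls,4,2020,107.0,5.1
height,girls,5,2000,109.9,5.8
height,girls,5,2005,111.0,5.7
height,girls,5,2010,112.4,5.4
height,girls,5,2014,112.7,5.3
height,girls,5,2020,114.1,5.2
height,girls,6,2000,114.4,5.8
height,girls,6,2005,116.1,5.5
height,girls,6,2010,117.0,5.6
height,girls,6,2014,118.1,5.5
height,girls,6,2020,118.5,5.4
weight,boys,3,2000,15.5,2.0
weight,boys,3,2005,16.0,2.3
weight,boys,3,2010,16.4,2.4
weight,boys,3,2014,16.6,2.4
weight,boys,3,2020,16.4,2.3
weight,boys,4,2000,17.2,2.4
weight,boys,4,2005,17.7,2.7
weight,boys,4,2010,18.1,2.9
weight,boys,4,2014,18.3,2.8
weight,boys,4,2020,18.4,2.5
weight,boys,5,2000,19.0,3.0
weight,boys,5,2005,19.7,3.4
weight,boys,5,2010,20.5,3.6
weight,boys,5,2014,20.6,3.5
weight,boys,5,2020,21.4,2.9
weight,boys,6,2000,20.6,3.3
weight,boys,6,2005,21.6,3.9
weight,boys,6,2010,22.5,4.3
weight,boys,6,2014,23.0,4.4
weight,boys,6,2020,23.1,3.2
weight,girls,3,2000,14.9,2.0
weight,girls,3,2005,15.4,2.1
weight,girls,3,2010,15.7,2.2
weight,girls,3,2014,15.9,2.1
weight,girls,3,2020,15.8,2.4
weight,girls,4,2000,16.5,2.3
weight,girls,4,2005,16.9,2.4
weight,girls,4,2010,17.4,2.7
weight,girls,4,2014,17.5,2.6
weight,girls,4,2020,17.7,2.5
weight,girls,5,2000,18.2,2.7
weight,girls,5,2005,18.8,3.0
weight,girls,5,2010,19.5,3.2
weight,girls,5,2014,19.6,3.2
weight,girls,5,2020,20.2,2.8
weight,girls,6,2000,19.6,3.0
weight,girls,6,2005,20.5,3.5
weight,girls,6,2010,21.1,3.6
weight,girls,6,2014,21.6,3.6
weight,girls,6,2020,21.9,3.1
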