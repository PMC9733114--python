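setting,year,dimension,measure,estimate,ui_low,ui_high
Ghana,2011,Economic status,D,-35.6,-47.1,-24.2
Ghana,2011,Economic status,R,0.3,0.2,0.6
Ghana,2011,Economic status,PAR,0,-6.4,6.4
Ghana,2011,Economic status,PAF,0,-19.6,19.6
Ghana,2011,Education,D,-15.3,-25.3,-5.3
Ghana,2011,Education,R,0.6,0.5,0.9
Ghana,2011,Education,PAR,0,-5.2,5.2
Ghana,2011,Education,PAF,0,-16,16
Ghana,2011,Place of residence,D,-24.8,-33,-16.6
Ghana,2011,Place of residence,R,0.4,0.3,0.6
Ghana,2011,Place of residence,PAR,0,-2.9,2.9
Ghana,2011,Place of residence,PAF,0,-8.9,8.9
Ghana,2011,Sub-national region,D,50.5,30.7,70.4
Ghana,2011,Sub-national region,R,5.3,2.2,12.7
Ghana,2011,Sub-national region,PAR,29.7,23.6,35.9
Ghana,2011,Sub-national region,PAF,91.3,72.3,110.3
Ghana,2017,Economic status,D,-35.7,-50,-21.5
Ghana,2017,Economic status,R,0.5,0.3,0.7
Ghana,2017,Economic status,PAR,0,-6.3,6.3
Ghana,2017,Economic status,PAF,0,-12.7,12.7
Ghana,2017,Education,D,-13.4,-25.4,-1.4
Ghana,2017,Education,R,0.8,0.6,0.9
Ghana,2017,Education,PAR,0,-5.5,5.5
Ghana,2017,Education,PAF,0,-11.1,11.1
Ghana,2017,Place of residence,D,-26.1,-35.6,-16.5
Ghana,2017,Place of residence,R,0.6,0.5,0.7
Ghana,2017,Place of residence,PAR,0,-3.1,3.1
Ghana,2017,Place of residence,PAF,0,-6.2,6.2
Ghana,2017,Sub-national region,D,58,42.2,73.8
Ghana,2017,Sub-national region,R,4.3,2.2,8.4
Ghana,2017,Sub-national region,PAR,25.8,18,33.6
Ghana,2017,Sub-national region,PAF,51.9,36.2,67.6
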