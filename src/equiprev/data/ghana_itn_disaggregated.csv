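setting,year,dimension,subgroup,estimate,se,ci_low,ci_high,n,pop_share
Ghana,2011,Economic status,Quintile 1 (poorest),51.4,,44.3,58.4,185,
Ghana,2011,Economic status,Quintile 2,49.7,,39.4,60.1,150,
Ghana,2011,Economic status,Quintile 3,31.9,,22.9,42.5,150,
Ghana,2011,Economic status,Quintile 4,12.9,,7.8,20.5,166,
Ghana,2011,Economic status,Quintile 5 (richest),15.8,,8.7,26.9,160,
Ghana,2011,Education,No formal education,42.2,,34.5,50.2,236,
Ghana,2011,Education,Primary school,33,,24.4,43,166,
Ghana,2011,Education,Secondary/higher education,26.9,,21.2,33.4,409,
Ghana,2011,Place of residence,Rural,43.6,,38.6,48.7,451,
Ghana,2011,Place of residence,Urban,18.8,,13.2,26.1,360,
Ghana,2011,Sub-national region,Ashanti,21.3,,12.3,34.4,186,
Ghana,2011,Sub-national region,Brong Ahafo,36.1,,23.6,50.9,72,
Ghana,2011,Sub-national region,Central,29.3,,21.2,39.1,81,
Ghana,2011,Sub-national region,Eastern,62.3,,44.2,77.6,71,
Ghana,2011,Sub-national region,Greater Accra,11.8,,5,25.5,107,
Ghana,2011,Sub-national region,Northern,37.9,,30.7,45.7,86,
Ghana,2011,Sub-national region,Upper East,50.5,,42.3,58.6,32,
Ghana,2011,Sub-national region,Upper West,41.2,,31.4,51.8,22,
Ghana,2011,Sub-national region,Volta,57.8,,46.4,68.4,74,
Ghana,2011,Sub-national region,Western,21.5,,11.5,36.5,80,
Ghana,2017,Economic status,Quintile 1 (poorest),65.1,,54.1,74.6,187,
Ghana,2017,Economic status,Quintile 2,59.1,,46.1,71,196,
Ghana,2017,Economic status,Quintile 3,50.8,,37.4,64.2,180,
Ghana,2017,Economic status,Quintile 4,43.2,,33.2,53.9,188,
Ghana,2017,Economic status,Quintile 5 (richest),29.4,,20.5,40,182,
Ghana,2017,Education,No formal education,56.8,,46.4,66.6,235,
Ghana,2017,Education,Primary school,60.2,,48.8,70.5,165,
Ghana,2017,Education,Secondary/higher education,43.4,,37.2,49.7,534,
Ghana,2017,Place of residence,Rural,61.5,,54.3,68.3,510,
Ghana,2017,Place of residence,Urban,35.5,,29.2,42.2,423,
Ghana,2017,Sub-national region,Ashanti,47,,36.4,57.8,263,
Ghana,2017,Sub-national region,Brong Ahafo,60.9,,46.3,73.8,92,
Ghana,2017,Sub-national region,Central,44.5,,31,58.8,69,
Ghana,2017,Sub-national region,Eastern,53.6,,39.3,67.3,91,
Ghana,2017,Sub-national region,Greater Accra,17.5,,8.8,31.7,92,
Ghana,2017,Sub-national region,Northern,49.1,,36.5,61.9,113,
Ghana,2017,Sub-national region,Upper East,75.5,,62.8,84.9,29,
Ghana,2017,Sub-national region,Upper West,61.8,,48.6,73.4,22,
Ghana,2017,Sub-national region,Volta,69.4,,48.4,84.5,76,
Ghana,2017,Sub-national region,Western,52.5,,36.1,68.3,88,
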