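location,source,season,rate,loq,ammonium,nitrate,oxygen,ph,specific_conductance,n2o_saturation,ch4_saturation,date
Blackstrap Reservoir,this_study,winter_ice,-1.7*,4.9 x 10−3,<86,<57,7.6,5.7,1237,134.8,97.6,2015-03-05
Buffalo Pound Lake,this_study,winter_ice,-4.0*,4.0 x 10−3,<86,<57,12.5,7.6,1185,184.8,246.1,2015-03-10
Echo Lake,this_study,winter_ice,1.2,7.0 x 10−2,366,171,8.3,8.6,1726,213.7,241.5,2016-02-02
Katepwa Lake,this_study,winter_ice,32,2.7 x 10−2,<86,620,9.9,6.8,1566,636.2,414.9,2015-03-10
Lenore Lake,this_study,winter_ice,-1.7*,6.8 x 10−3,263,200,7.5,8.4,3758,253,259.3,2015-03-25
Mission Lake,this_study,winter_ice,2.1,1.1 x 10−1,452,129,7.6,8.5,1790,195.4,282.1,2016-02-02
Pasqua Lake,this_study,winter_ice,870.7,3.2 x 10−3,1650,532,8.6,7.3,2180,671,178,2015-03-10
St. Denis Pond 1,this_study,winter_ice,-0.042*,3.2 x 10−3,<86,<57,10,6.9,1536,132.9,1109.3,2015-04-16
St. Denis Pond 5338,this_study,winter_ice,-0.044*,3.1 x 10−3,<86,<57,15,8.2,2963,135.7,1027.6,2015-04-16
St. Denis Pond 90,this_study,winter_ice,-0.1*,3.6 x 10−3,<86,<57,14.5,8.6,1648,109.1,1650.2,2015-04-16
St. Brieux Lake,this_study,winter_ice,110,1.8 x 10−3,528,310,2,7.8,3589,515.6,579.8,2015-03-25
ELA Lake 227,this_study,winter_ice,0.14,4.6 x 10−5,516,314,5.84,6,26,,,2016-03-14
ELA Lake 239,this_study,winter_ice,0.022,1.2 x 10−4,636,145,13.7,6.6,30,,,2016-03-14
Lake St. George,st_george,winter_ice,22.8,,467,540,9.3,,,,,1980-02-27
Lake St. George,st_george,winter_ice,12.2,,390,550,8.1,,,,,1980-03-06
Lake St. George,st_george,winter_ice,4.5,,65,1230,1.3,,,,,1982-02-24
Lake St. George,st_george,winter_ice,1.3,,39,1191,0.8,,,,,1982-03-01
Lake St. George,st_george,winter_ice,10.5,,490,210,10.2,,,,,1983-02-09
Lake Croche,croche,winter_ice,4.7,,38,19,,,,,,2012-02-01
Lake Croche,croche,winter_ice,2.6,,38,27,,,,,,2012-03-01
Allequash Lake,wisconsin,winter_ice,0.58,,,,,,,,,
Big Musky Lake,wisconsin,winter_ice,0.55,,,,,,,,,
Crystal Lake,wisconsin,winter_ice,0.39,,,,,,,,,
Sparkling Lake,wisconsin,winter_ice,0.45,,,,,,,,,
Trout Lake,wisconsin,winter_ice,0.87,,,,,,,,,
Western Basin of Lake Superior,superior,winter_no_ice,0.34,,2.55,,,,,,,2009-11-11
Western Basin of Lake Superior,superior,winter_no_ice,0.03,,2.25,,,,,,,2011-03-20
Western Basin of Lake Superior,superior,summer,0.11,,1.8,,,,,,,2010-06-27
Western Basin of Lake Superior,superior,summer,0.33,,4.35,,,,,,,2010-08-19
Lake Croche,croche,summer,0.81,,22.5,45.6,,,,,,2012-05-01
Lake Croche,croche,summer,0.49,,7,28,,,,,,2012-05-27
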