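species,population,period,afr,fledglings_mean,fledglings_sd,param_kind,age_class,mean,sd
Common Starling,Netherlands,1960-1978,1,2.56,0,survival,first_year,0.331,0.035
Common Starling,Netherlands,1960-1978,1,2.56,0,survival,second_year,0.677,0.049
Common Starling,Netherlands,1960-1978,1,2.56,0,survival,older,0.677,0.049
Common Starling,Netherlands,1960-1978,1,2.56,0,breeding_prob,1,1,0
Common Starling,Netherlands,1978-1990,1,4.17,0.238,survival,first_year,0.181,0.051
Common Starling,Netherlands,1978-1990,1,4.17,0.238,survival,second_year,0.615,0.039
Common Starling,Netherlands,1978-1990,1,4.17,0.238,survival,older,0.615,0.039
Common Starling,Netherlands,1978-1990,1,4.17,0.238,breeding_prob,1,1,0
Common Starling,Netherlands,1990-2012,1,3.73,0.546,survival,first_year,0.102,0.034
Common Starling,Netherlands,1990-2012,1,3.73,0.546,survival,second_year,0.607,0.151
Common Starling,Netherlands,1990-2012,1,3.73,0.546,survival,older,0.607,0.151
Common Starling,Netherlands,1990-2012,1,3.73,0.546,breeding_prob,1,1,0
Black-tailed Godwit,Kuststrook,2011-2016,2,1.8,0.618,survival,first_year,0.169,0.074
Black-tailed Godwit,Kuststrook,2011-2016,2,1.8,0.618,survival,second_year,0.858,0.007
Black-tailed Godwit,Kuststrook,2011-2016,2,1.8,0.618,survival,older,0.858,0.007
Black-tailed Godwit,Kuststrook,2011-2016,2,1.8,0.618,breeding_prob,2,1,0
Black-tailed Godwit,Skriezekrite,2012-2016,2,2.461,0.787,survival,first_year,0.169,0.113
Black-tailed Godwit,Skriezekrite,2012-2016,2,2.461,0.787,survival,second_year,0.859,0.007
Black-tailed Godwit,Skriezekrite,2012-2016,2,2.461,0.787,survival,older,0.859,0.007
Black-tailed Godwit,Skriezekrite,2012-2016,2,2.461,0.787,breeding_prob,2,1,0
Marsh Harrier,Netherlands,1997-2015,3,2.124,0.409,survival,first_year,0.641,0.093
Marsh Harrier,Netherlands,1997-2015,3,2.124,0.409,survival,second_year,0.804,0.063
Marsh Harrier,Netherlands,1997-2015,3,2.124,0.409,survival,older,0.804,0.063
Marsh Harrier,Netherlands,1997-2015,3,2.124,0.409,breeding_prob,3,0.5,0
Eurasian Spoonbill,Netherlands,1994-2008,4,1.859,0.696,survival,first_year,0.607,0.126
Eurasian Spoonbill,Netherlands,1994-2008,4,1.859,0.696,survival,second_year,0.893,0.026
Eurasian Spoonbill,Netherlands,1994-2008,4,1.859,0.696,survival,older,0.877,0.01
Eurasian Spoonbill,Netherlands,1994-2008,4,1.859,0.696,breeding_prob,4,0.63,0
Eurasian Spoonbill,Netherlands,1994-2008,4,1.859,0.696,breeding_prob,5,0.79,0
Eurasian Spoonbill,Netherlands,1994-2008,4,1.859,0.696,breeding_prob,6,0.95,0
White Stork,Switzerland,1977-2000,3,1.56,0.463,survival,first_year,0.39,0.096
White Stork,Switzerland,1977-2000,3,1.56,0.463,survival,second_year,0.861,0.047
White Stork,Switzerland,1977-2000,3,1.56,0.463,survival,older,0.861,0.047
White Stork,Switzerland,1977-2000,3,1.56,0.463,breeding_prob,3,0.475,0
White Stork,Switzerland,1977-2000,3,1.56,0.463,breeding_prob,4,0.65,0
White Stork,Switzerland,1977-2000,3,1.56,0.463,breeding_prob,5,0.825,0
White Stork,Switzerland,1977-2000,3,1.56,0.463,breeding_prob,6,1,0
Common Tern,IJsselmeer,1994-2008,4,1.294,1.024,survival,first_year,0.555,0.186
Common Tern,IJsselmeer,1994-2008,4,1.294,1.024,survival,second_year,0.588,0.208
Common Tern,IJsselmeer,1994-2008,4,1.294,1.024,survival,older,0.724,0.131
Common Tern,IJsselmeer,1994-2008,4,1.294,1.024,breeding_prob,4,1,0
White-tailed Eagle,Schleswig-Holstein,1947-1974,5,0.454,0.278,survival,first_year,0.72,0
White-tailed Eagle,Schleswig-Holstein,1947-1974,5,0.454,0.278,survival,second_year,0.889,0
White-tailed Eagle,Schleswig-Holstein,1947-1974,5,0.454,0.278,survival,older,0.816,0
White-tailed Eagle,Schleswig-Holstein,1947-1974,5,0.454,0.278,breeding_prob,5,0.954,0
White-tailed Eagle,Schleswig-Holstein,1975-2008,5,1.573,0.387,survival,first_year,0.741,0
White-tailed Eagle,Schleswig-Holstein,1975-2008,5,1.573,0.387,survival,second_year,0.8,0
White-tailed Eagle,Schleswig-Holstein,1975-2008,5,1.573,0.387,survival,older,0.813,0
White-tailed Eagle,Schleswig-Holstein,1975-2008,5,1.573,0.387,breeding_prob,5,0.954,0
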