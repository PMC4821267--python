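location,country,n,min_m,max_m,mean_m,mean_method,period_start,period_end,techniques,notes
Christmas Island,Australia,82,2.5,8,4.6,reported,2007,2008,unspecified,
Ningaloo Reef,Australia,,2,13,7.35,reported,1995,1996,visual,n printed as <500 from size-frequency graphs; mean estimated for 1997
Ningaloo Reef,Australia,,2,10,6.7,reported,2003,2004,visual,n printed as <500 from size-frequency graphs
Ningaloo Reef,Australia,123,2,8,5,reported,2009,2011,visual,this study
Gladden Spit,Belize,25,3,13,8,mean_of_range,1998,1998,visual,
Gladden Spit,Belize,317,3,12.7,6.3,reported,1998,2003,visual,
St Peter St Paul,Brazil,54,1.8,14,7.2,from_size_frequency,2000,2005,visual,
Gulf of Tadjura,Djibouti,19,2.5,6,4.5,reported,2006,2006,visual,
Gulf of Tadjura,Djibouti,232,2.5,7,3.8,reported,2003,2010,visual,
Galapagos Islands,Ecuador,4,5.6,11.2,8.95,reported,2011,2012,photogrammetry;aerial_vehicle_comparison,
Galapagos Islands,Ecuador,82,4,13.1,11.35,reported,2011,2013,photogrammetry,
Utila Bay Islands,Honduras,95,2,11,6.5,reported,1999,2011,visual,
Several locations,India,164,3.15,14.5,5.5,reported,1998,1998,unspecified,period printed as <1998
South Ari Atoll,Maldives,64,2.5,10.5,5.98,reported,2006,2008,visual,
Bahia de Los Angeles,Mexico,19,3,10,5.4,reported,1999,1999,visual,
Bahia de Los Angeles,Mexico,129,2.5,9,5,reported,2003,2009,visual,
Bahia de Los Angeles,Mexico,30,3,10,6,reported,2003,2003,visual,period printed as <2003
Bahia de La Paz,Mexico,125,2,7,4,reported,2003,2009,visual,
Gorda Banks,Mexico,15,9,12,4,reported,2003,2010,visual;aerial_vehicle_comparison,mean outside printed range; transcribed as printed
Island Espiritu Santo,Mexico,8,10.5,13,4,reported,2003,2010,visual;aerial_vehicle_comparison,mean outside printed range; transcribed as printed
Gulf of Mexico,Mexico,16,6,12,8,reported,2006,2006,visual,
Holbox,Mexico,330,2.5,9.5,6,mean_of_range,2005,2008,visual,
Yucatan Peninsula,Mexico,33,4.5,8.5,6.5,from_size_frequency,2006,2008,photogrammetry,
North Island,New Zealand,26,3.5,15,8.15,reported,1980,2001,unspecified,
Al-Lith,Saudi Arabia,64,2.5,7,4.00,reported,2009,2011,visual,
Mahe Island,Seychelles,549,3,10.5,6,reported,2001,2009,visual,
Mafia Island,Tanzania,56,4.20,9.90,6.55,reported,2012,2013,photogrammetry,
Praia do Tofu,Mozambique,123,4.34,9.34,6.84,reported,2010,2013,photogrammetry,
KwaZulu-Natal,South Africa,36,3,11,6.1,reported,1984,1995,vertebral_rings,
KwaZulu-Natal,South Africa,38,4,7,5.5,from_size_frequency,2001,2005,visual,
KwaZulu-Natal,South Africa,15,5.4,9.5,7.5,from_size_frequency,1991,1998,visual,
around Taiwan,Taiwan,597,1,13,4.6,mean_of_range,1995,2008,visual,mean flagged mean-of-range but differs from range midpoint 7; transcribed as printed
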