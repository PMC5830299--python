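sdr_id,sdr_type,sex,standard_length_cm,axillary_girth_cm,max_girth_cm,date_captured,date_entered_bering,date_last_location,duration_days,days_with_location,location_days_bering,used_in_habitat
53604,SPLASH,F,,,,2004-10-05,,2005-02-01,120,90,0,0
53605,SPLASH,F,,,,2004-10-11,,2004-12-02,53,49,0,0
53606,SPLASH,M,148,113,123,2005-09-24,2005-11-10,2006-04-01,190,157,141,1
53607,SPLASH,F,141,97,110,2005-09-24,2005-11-16,2006-02-08,138,105,84,1
53609,SPLASH,M,140,123,122,2005-09-26,,2006-06-05,253,149,0,0
53608,SPLASH,M,142,,,2005-09-30,2005-11-09,2005-11-26,58,55,18,1
53610,SPLASH,M,166,,,2005-10-01,2005-12-21,2006-04-30,212,176,109,1
53611,SPLASH,M,141,,,2005-10-02,2005-12-02,2006-01-15,106,84,33,1
59971,SPLASH,F,143,115,,2005-10-02,2005-12-02,2005-12-27,87,81,24,1
59970,SPLASH,M,129,,,2005-10-03,,2006-04-20,200,170,0,0
59972,SPLASH,F,149,110,115,2005-10-04,2005-11-09,2006-03-30,178,176,141,1
59968,SPLASH,F,135,,,2005-10-07,2005-10-27,2006-05-04,210,168,148,1
59969,SPLASH,M,145,121,125,2005-10-07,2005-10-22,2005-11-19,44,39,25,1
59973,SPLASH,F,134,,,2005-10-07,,2006-01-07,93,77,0,0
59974,SPLASH,F,140,96,106,2005-10-07,2005-11-07,2006-02-22,139,95,67,1
59976,SPLASH,M,157,129,131,2005-10-07,2005-10-20,2006-02-02,119,82,66,1
59967,SPLASH,F,126,,,2005-10-11,,2005-10-15,5,5,0,0
58069,SPLASH,F,150,113,124,2006-10-03,2006-11-21,2007-05-26,236,216,172,1
70413,CTD,M,138,102,118,2006-10-06,,2006-10-09,4,2,0,0
58059,SPLASH,M,134,102,114,2006-10-07,2006-11-11,2007-05-04,210,190,162,1
70414,CTD,M,136,108,114,2006-10-07,,2006-10-12,5,5,0,0
70415,CTD,F,139,108,120,2006-10-07,,2006-10-26,19,14,0,0
70416,CTD,F,144,118,138,2006-10-07,2006-11-08,2006-12-18,73,57,28,1
70417,CTD,M,151,120,133,2006-10-07,2006-12-07,2006-12-31,86,62,22,1
58060,SPLASH,F,137,116,128,2006-10-20,2006-11-12,2007-01-18,91,88,68,1
65914,SPLASH,M,148,100,109,2006-10-22,2006-11-06,2006-12-22,62,60,46,1
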