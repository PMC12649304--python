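drug_id,dose_ug,ee_dose_ug,bmi_group,inducer,cavg_ng_ml,gcv_percent
DRSP,500,0,lt25,none,5.47,30.0
DRSP,500,0,lt25,CBZ400,2.735,30.0
DRSP,500,0,lt25,RIF600,2.188,30.0
DRSP,500,0,25to30,none,4.8136,30.0
DRSP,500,0,25to30,CBZ400,2.4068,30.0
DRSP,500,0,25to30,RIF600,1.9254,30.0
DRSP,500,0,ge30,none,4.4854,30.0
DRSP,500,0,ge30,CBZ400,2.2427,30.0
DRSP,500,0,ge30,RIF600,1.7942,30.0
DRSP,1000,0,lt25,none,10.93,30.0
DRSP,1000,0,lt25,CBZ400,5.465,30.0
DRSP,1000,0,lt25,RIF600,4.372,30.0
DRSP,1000,0,25to30,none,9.6184,30.0
DRSP,1000,0,25to30,CBZ400,4.8092,30.0
DRSP,1000,0,25to30,RIF600,3.8474,30.0
DRSP,1000,0,ge30,none,8.9626,30.0
DRSP,1000,0,ge30,CBZ400,4.4813,30.0
DRSP,1000,0,ge30,RIF600,3.585,30.0
DRSP,2000,0,lt25,none,21.86,30.0
DRSP,2000,0,lt25,CBZ400,10.93,30.0
DRSP,2000,0,lt25,RIF600,8.744,30.0
DRSP,2000,0,25to30,none,19.2368,30.0
DRSP,2000,0,25to30,CBZ400,9.6184,30.0
DRSP,2000,0,25to30,RIF600,7.6947,30.0
DRSP,2000,0,ge30,none,17.9252,30.0
DRSP,2000,0,ge30,CBZ400,8.9626,30.0
DRSP,2000,0,ge30,RIF600,7.1701,30.0
DRSP,3000,0,lt25,none,32.79,30.0
DRSP,3000,0,lt25,CBZ400,16.395,30.0
DRSP,3000,0,lt25,RIF600,13.116,30.0
DRSP,3000,0,25to30,none,28.8552,30.0
DRSP,3000,0,25to30,CBZ400,14.4276,30.0
DRSP,3000,0,25to30,RIF600,11.5421,30.0
DRSP,3000,0,ge30,none,26.8878,30.0
DRSP,3000,0,ge30,CBZ400,13.4439,30.0
DRSP,3000,0,ge30,RIF600,10.7551,30.0
DRSP,3000,20,lt25,none,32.79,30.0
DRSP,3000,20,lt25,CBZ400,16.395,30.0
DRSP,3000,20,lt25,RIF600,13.116,30.0
DRSP,3000,20,25to30,none,28.8552,30.0
DRSP,3000,20,25to30,CBZ400,14.4276,30.0
DRSP,3000,20,25to30,RIF600,11.5421,30.0
DRSP,3000,20,ge30,none,26.8878,30.0
DRSP,3000,20,ge30,CBZ400,13.4439,30.0
DRSP,3000,20,ge30,RIF600,10.7551,30.0
DRSP,3000,30,lt25,none,33.5,30.0
DRSP,3000,30,lt25,CBZ400,16.75,30.0
DRSP,3000,30,lt25,RIF600,13.4,30.0
DRSP,3000,30,25to30,none,29.48,30.0
DRSP,3000,30,25to30,CBZ400,14.74,30.0
DRSP,3000,30,25to30,RIF600,11.792,30.0
DRSP,3000,30,ge30,none,27.47,30.0
DRSP,3000,30,ge30,CBZ400,13.735,30.0
DRSP,3000,30,ge30,RIF600,10.988,30.0
DRSP,4000,0,lt25,none,43.72,30.0
DRSP,4000,0,lt25,CBZ400,21.86,30.0
DRSP,4000,0,lt25,RIF600,17.488,30.0
DRSP,4000,0,25to30,none,38.4736,30.0
DRSP,4000,0,25to30,CBZ400,19.2368,30.0
DRSP,4000,0,25to30,RIF600,15.3894,30.0
DRSP,4000,0,ge30,none,35.8504,30.0
DRSP,4000,0,ge30,CBZ400,17.9252,30.0
DRSP,4000,0,ge30,RIF600,14.3402,30.0
LNG,30,0,lt25,none,0.54,30.0
LNG,30,0,lt25,CBZ400,0.27,30.0
LNG,30,0,lt25,RIF600,0.216,30.0
LNG,30,0,25to30,none,0.4752,30.0
LNG,30,0,25to30,CBZ400,0.2376,30.0
LNG,30,0,25to30,RIF600,0.1901,30.0
LNG,30,0,ge30,none,0.4428,30.0
LNG,30,0,ge30,CBZ400,0.2214,30.0
LNG,30,0,ge30,RIF600,0.1771,30.0
LNG,90,20,lt25,none,2.18,30.0
LNG,90,20,lt25,CBZ400,1.09,30.0
LNG,90,20,lt25,RIF600,0.872,30.0
LNG,90,20,25to30,none,1.9184,30.0
LNG,90,20,25to30,CBZ400,0.9592,30.0
LNG,90,20,25to30,RIF600,0.7674,30.0
LNG,90,20,ge30,none,1.7876,30.0
LNG,90,20,ge30,CBZ400,0.8938,30.0
LNG,90,20,ge30,RIF600,0.715,30.0
LNG,100,20,lt25,none,2.42,30.0
LNG,100,20,lt25,CBZ400,1.21,30.0
LNG,100,20,lt25,RIF600,0.968,30.0
LNG,100,20,25to30,none,2.1296,30.0
LNG,100,20,25to30,CBZ400,1.0648,30.0
LNG,100,20,25to30,RIF600,0.8518,30.0
LNG,100,20,ge30,none,1.9844,30.0
LNG,100,20,ge30,CBZ400,0.9922,30.0
LNG,100,20,ge30,RIF600,0.7938,30.0
LNG,150,30,lt25,none,3.63,30.0
LNG,150,30,lt25,CBZ400,1.815,30.0
LNG,150,30,lt25,RIF600,1.452,30.0
LNG,150,30,25to30,none,3.1944,30.0
LNG,150,30,25to30,CBZ400,1.5972,30.0
LNG,150,30,25to30,RIF600,1.2778,30.0
LNG,150,30,ge30,none,2.9766,30.0
LNG,150,30,ge30,CBZ400,1.4883,30.0
LNG,150,30,ge30,RIF600,1.1906,30.0
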