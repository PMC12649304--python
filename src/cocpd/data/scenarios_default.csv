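drug_id,dose_ug,ee_dose_ug,bmi_group,inducer,n_virtual,seed,is_reference
LNG,100,20,lt25,none,100,1000,true
LNG,100,20,lt25,CBZ400,100,1001,false
LNG,100,20,lt25,RIF600,100,1002,false
LNG,100,20,25to30,none,100,1003,true
LNG,100,20,25to30,CBZ400,100,1004,false
LNG,100,20,25to30,RIF600,100,1005,false
LNG,100,20,ge30,none,100,1006,true
LNG,100,20,ge30,CBZ400,100,1007,false
LNG,100,20,ge30,RIF600,100,1008,false
LNG,150,30,lt25,none,100,1009,true
LNG,150,30,lt25,CBZ400,100,1010,false
LNG,150,30,lt25,RIF600,100,1011,false
LNG,150,30,25to30,none,100,1012,true
LNG,150,30,25to30,CBZ400,100,1013,false
LNG,150,30,25to30,RIF600,100,1014,false
LNG,150,30,ge30,none,100,1015,true
LNG,150,30,ge30,CBZ400,100,1016,false
LNG,150,30,ge30,RIF600,100,1017,false
DRSP,3000,20,lt25,none,100,1018,true
DRSP,3000,20,lt25,CBZ400,100,1019,false
DRSP,3000,20,lt25,RIF600,100,1020,false
DRSP,3000,20,25to30,none,100,1021,true
DRSP,3000,20,25to30,CBZ400,100,1022,false
DRSP,3000,20,25to30,RIF600,100,1023,false
DRSP,3000,20,ge30,none,100,1024,true
DRSP,3000,20,ge30,CBZ400,100,1025,false
DRSP,3000,20,ge30,RIF600,100,1026,false
DRSP,3000,30,lt25,none,100,1027,true
DRSP,3000,30,lt25,CBZ400,100,1028,false
DRSP,3000,30,lt25,RIF600,100,1029,false
DRSP,3000,30,25to30,none,100,1030,true
DRSP,3000,30,25to30,CBZ400,100,1031,false
DRSP,3000,30,25to30,RIF600,100,1032,false
DRSP,3000,30,ge30,none,100,1033,true
DRSP,3000,30,ge30,CBZ400,100,1034,false
DRSP,3000,30,ge30,RIF600,100,1035,false
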