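probe_id,class,ctrl1,ctrl2,ctrl3,ctrl4,ctrl5,ctrl6,ctrl7,kd1,kd2,kd3,kd4
mirE1,endogenous,100,100,100,100,100,100,100,100,100,100,100
mirE2,endogenous,50,50,50,50,50,50,0,0,0,0,0
mirE3,endogenous,30,30,30,30,30,0,0,25,25,0,0
mirE4,endogenous,0,0,0,0,0,0,0,40,40,40,0
mirE5,endogenous,0,0,0,0,0,0,0,0,0,0,0
mirE6,endogenous,80,80,80,80,80,80,80,0,0,0,0
POS_A,positive,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000,1000
POS_B,positive,250,250,250,250,250,250,250,250,250,250,250
NEG_A,negative,0,0,0,0,0,0,0,0,0,0,0
NEG_B,negative,0,0,0,0,0,0,0,0,0,0,0
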