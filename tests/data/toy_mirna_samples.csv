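sample,condition,replicate
ctrl1,nt_prolif,1
ctrl2,nt_prolif,2
ctrl3,nt_prolif,3
ctrl4,nt_prolif,4
ctrl5,nt_prolif,5
ctrl6,nt_prolif,6
ctrl7,nt_prolif,7
kd1,kd,1
kd2,kd,2
kd3,kd,3
kd4,kd,4
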