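participant_id,age,sex,batch
P1,79.9,0.0,1.5T
P2,82.7,1.0,1.5T
P3,76.7,0.0,1.5T
P4,83.7,1.0,1.5T
P5,80.4,1.0,3T
P6,74.1,0.0,3T
P7,75.8,1.0,3T
P8,67.5,0.0,3T
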