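participant_id,feat1,feat2,feat3
P1,2.446386,2.912525,3280.808763
P2,2.461935,2.770321,4047.630603
P3,2.446502,2.688566,3670.224556
P4,2.519077,3.211454,3741.086116
P5,2.445722,3.140689,3456.526766
P6,2.30577,2.774815,3805.599432
P7,2.696765,2.937666,3847.078555
P8,2.393497,3.241197,3698.3552
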