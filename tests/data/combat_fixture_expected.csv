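participant_id,feat1,feat2,feat3
P1,2.3976774700047851,2.8633627409561608,3184.7138211847555
P2,2.4243366462397935,2.7488252929761554,3918.8739539937033
P3,2.4010289925136101,2.6643167193062749,3556.9327549895042
P4,2.4766817486825725,3.1488580786538520,3631.1047728840499
P5,2.4957147983997849,3.1614027677031902,3600.6050315010248
P6,2.3574996750473742,2.8374846085873031,3865.7137587659304
P7,2.7159316920633740,3.0038394027570723,3962.2510205738740
P8,2.4474966092530153,3.2461006922372597,3829.3535644920375
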