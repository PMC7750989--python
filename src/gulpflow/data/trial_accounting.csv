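trial_id,individual_id,food_type,head_length,frame_rate,includes_esophageal
t001,cat01,pellet,72.0,300,True
t002,cat01,pellet,72.0,300,True
t003,cat01,pellet,72.0,300,True
t004,cat01,pellet,72.0,300,True
t005,cat01,pellet,72.0,300,True
t006,cat01,pellet,72.0,300,False
t007,cat01,pellet,72.0,300,False
t008,cat01,pellet,72.0,300,False
t009,cat01,squid,72.0,300,False
t010,cat01,worm,72.0,300,True
t011,cat01,worm,72.0,300,False
t012,cat02,pellet,69.0,300,True
t013,cat02,pellet,69.0,300,True
t014,cat02,worm,69.0,300,True
t015,cat02,worm,69.0,300,True
t016,cat02,worm,69.0,300,True
t017,cat02,worm,69.0,300,True
t018,cat02,worm,69.0,300,True
t019,cat02,worm,69.0,300,False
t020,cat02,worm,69.0,300,False
t021,cat02,worm,69.0,300,False
t022,cat02,worm,69.0,300,False
t023,cat05,worm,71.0,300,True
t024,cat05,worm,71.0,300,True
t025,cat05,worm,71.0,300,True
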