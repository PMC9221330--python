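subject,stall,somersault,takeoff,turn_and_hover,level_flight,roll
Subject 1,10,8,6,6,4,3
Subject 2,7,6,8,5,3,4
Subject 3,8,9,5,6,4,4
Subject 4,9,8,3,5,3,3
Subject 5,8,5,2,3,2,2
Subject 6,8,4,1,4,1,3
Subject 7,6,8,1,5,2,2
Subject 8,3,7,2,3,3,6
Subject 9,8,9,5,6,5,5
Subject 10,7,8,3,6,4,4
Subject 11,8,7,3,5,4,3
Subject 12,5,7,2,6,5,2
Subject 13,7,9,3,7,5,3
Subject 14,8,8,4,5,4,3
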