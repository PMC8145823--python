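fish_id,setting,location,sex,total_length_cm,sunrise,sunset,recording_hours
C1,captive,Arno Bay,M,91,,,115
C2,captive,Arno Bay,F,105,,,115
C3,captive,Arno Bay,M,95,,,115
C4,captive,Arno Bay,M,90,,,93
C5,captive,Arno Bay,F,97,,,93
C6,captive,Arno Bay,M,101,,,93
FR1,free_ranging,Neptune Islands,,99,06:28,19:51,45.5
FR2,free_ranging,Neptune Islands,,98,06:28,19:51,37
FR3,free_ranging,Neptune Islands,,114,06:25,19:53,16.7
FR4,free_ranging,Neptune Islands,,120,06:56,20:22,10.7
FR5,free_ranging,Neptune Islands,,119,06:58,20:20,16.6
FR6,free_ranging,Coffin Bay,,151,06:19,20:05,51.2
FR7,free_ranging,Coffin Bay,,142,06:19,20:05,33.7
FR8,free_ranging,Coffin Bay,,140,06:19,20:05,30.3
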