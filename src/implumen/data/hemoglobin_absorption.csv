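wavelength_nm,mua_hbo2_per_m,mua_hb_per_m
400,0.202300,0.128565
410,0.204633,0.143936
420,0.208964,0.165728
430,0.216663,0.195634
440,0.229764,0.235335
450,0.251071,0.286270
460,0.284202,0.349352
470,0.333382,0.424652
480,0.403002,0.511112
490,0.496848,0.606335
500,0.617055,0.70653
510,0.762966,0.806648
520,0.930128,0.900737
530,1.109794,0.982496
540,1.289221,1.045959
550,1.452905,1.086207
560,1.58467,1.1
570,1.67029,1.086207
580,1.7,1.045959
590,1.67029,0.982496
600,1.58467,0.900737
610,1.452905,0.806648
620,1.289223,0.70653
630,1.10979,0.606335
640,0.930128,0.511112
650,0.762966,0.424652
660,0.617055,0.349352
670,0.496848,0.286270
680,0.403002,0.235335
690,0.333382,0.195634
700,0.284202,0.165728
710,0.251071,0.143936
720,0.229761,0.128565
730,0.216663,0.118063
740,0.208903,0.111108
750,0.204633,0.106645
760,0.202301,0.10386
770,0.201097,0.102187
780,0.200503,0.101201
790,0.200221,0.100645
800,0.200093,0.100335
810,0.200038,0.100169
820,0.200014,0.100083
830,0.200005,0.100040
840,0.200001,0.100018
850,0.200002,0.100008
860,0.200002,0.100003
870,0.200007,0.100001
880,0.200002,0.100006
890,0.200007,0.100002
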