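study_id,design,species,sex,year,n,centers_experimental,centers_nonexperimental,dual_role_centers
ML01,multilab,dog,both,,51,3,1,0
ML02,multilab,mouse,both,,384,3,0,0
ML03,multilab,swine,F,,60,3,0,0
ML04,multilab,swine,NR,,32,2,0,0
ML05,multilab,mouse,M,,47,3,3,0
ML05,multilab,rabbit,M,,23,3,3,0
ML05,multilab,swine,F,,26,3,3,0
ML06,multilab,mouse,M,,315,5,1,0
ML07,multilab,mouse,M,,241,5,1,1
ML08,multilab,rat,M,,140,3,1,0
ML09,multilab,rat,M,,130,3,1,0
ML10,multilab,rat,M,,135,3,1,0
ML11,multilab,mouse,F,,NR,4,0,0
ML12,multilab,rat,M,,128,3,1,0
ML13,multilab,rat,M,,142,3,1,0
ML14,multilab,rat,M,,72,3,0,0
ML15,multilab,rat,M,,111,3,1,0
ML16,multilab,mouse,M,,108,3,0,0
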