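site,diet_group,n_specimens,map_number
Funadomari,HOK,5,1
Takasago,HOK,4,2
Irie,HOK,2,3
Kotan Onsen,HOK,4,4
Kitakogane,HOK,4,5
Miyano,NEH,3,6
Ebishima,NEH,17,7
Wakaumi,CCH,1,8
Yoshigo,CCH,11,9
Ikawazu,CCH,4,10
Tochibara,ICH,3,11
Tsukumo,SWJ,20,12
Yamaga,SWJ,4,13
Einomaru,SWJ,1,14
Todoroki,SWJ,1,15
Goryo,SWJ,1,16
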