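,Funadomari,Takasago,Irie,Kotan Onsen,Kitakogane,Miyano,Ebishima,Wakaumi,Yoshigo,Ikawazu,Tochibara,Tsukumo,Yamaga,Einomaru,Todoroki,Goryo
Funadomari,0.00,311.60,312.72,319.25,327.87,685.03,724.36,1025.69,1227.76,1228.30,1049.08,1363.09,1548.88,1550.81,1665.80,1660.06
Takasago,311.60,0.00,22.57,34.68,18.86,377.91,414.37,714.10,926.78,927.41,743.05,1095.31,1306.10,1306.81,1413.60,1406.91
Irie,312.72,22.57,0.00,32.22,19.28,377.36,413.59,713.00,925.03,925.66,741.45,1093.08,1303.71,1304.43,1411.27,1404.59
Kotan Onsen,319.25,34.68,32.22,0.00,45.16,381.57,414.64,709.35,911.58,912.16,730.44,1071.37,1278.75,1279.61,1387.56,1381.00
Kitakogane,327.87,18.86,19.28,45.16,0.00,360.03,397.15,697.96,914.40,915.05,729.63,1087.74,1301.05,1301.64,1407.47,1400.69
Miyano,685.03,377.91,377.36,381.57,360.03,0.00,52.19,355.23,630.44,631.40,436.05,886.21,1137.98,1136.23,1220.82,1212.46
Ebishima,724.36,414.37,413.59,414.64,397.15,52.19,0.00,307.57,578.25,579.20,383.86,836.60,1090.24,1088.33,1171.33,1162.90
Wakaumi,1025.69,714.10,713.00,709.35,697.96,355.23,307.57,0.00,328.26,329.50,171.15,654.04,924.40,920.34,977.55,968.09
Yoshigo,1227.76,926.78,925.03,911.58,914.40,630.44,578.25,328.26,0.00,1.32,194.41,346.42,615.20,610.04,654.60,644.90
Ikawazu,1228.30,927.41,925.66,912.16,915.05,631.40,579.20,329.50,1.32,0.00,195.36,345.11,613.88,608.72,653.29,643.59
Tochibara,1049.08,743.05,741.45,730.44,729.63,436.05,383.86,171.15,194.41,195.36,0.00,489.10,757.89,754.21,818.24,809.05
Tsukumo,1363.09,1095.31,1093.08,1071.37,1087.74,886.21,836.60,654.04,346.42,345.11,489.10,0.00,270.90,266.50,334.77,326.30
Yamaga,1548.88,1306.10,1303.71,1278.75,1301.05,1137.98,1090.24,924.40,615.20,613.88,757.89,270.90,0.00,8.85,133.97,133.18
Einomaru,1550.81,1306.81,1304.43,1279.61,1301.64,1136.23,1088.33,920.34,610.04,608.72,754.21,266.50,8.85,0.00,128.12,126.84
Todoroki,1665.80,1413.60,1411.27,1387.56,1407.47,1220.82,1171.33,977.55,654.60,653.29,818.24,334.77,133.97,128.12,0.00,10.10
Goryo,1660.06,1406.91,1404.59,1381.00,1400.69,1212.46,1162.90,968.09,644.90,643.59,809.05,326.30,133.18,126.84,10.10,0.00
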