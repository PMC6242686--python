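genotype,x_day,y_kpix,slope1,slope2
Alma,20.40,104.50,9.18,42.16
Bluey,26.11,89.69,5.71,23.03
Bohatyr,24.48,166.20,12.06,40.04
Bonzer,25.79,93.86,6.10,21.44
Bundi,25.77,90.49,5.83,19.20
Collegian,25.52,209.20,13.65,47.16
Cooke,25.65,189.00,12.84,56.16
Cressy Blue,23.42,160.50,12.60,49.27
Derrimut,23.50,159.50,12.31,48.08
Dinkum,25.83,108.43,7.32,27.95
Dunn,22.40,138.40,11.30,32.93
Dundale,24.43,156.80,11.15,39.22
Dunwa,23.52,124.82,8.95,30.77
Excell,25.81,95.75,6.16,23.26
Glenroy,25.63,161.81,10.48,34.41
Helena,25.53,145.73,10.05,40.03
Jupiter,24.41,113.94,7.92,29.52
Kaspa,25.61,91.73,5.86,20.26
Kiley,25.64,97.58,6.36,19.34
King,26.22,107.66,6.65,30.91
Laura,25.63,165.30,11.37,45.51
Magnet,25.56,93.93,6.32,23.98
Maitland,25.80,137.93,8.62,31.56
Maki,26.01,84.65,5.33,20.33
Moonlight,25.59,97.33,6.27,21.78
Morgan,25.88,110.42,6.90,24.94
Mukta,26.26,78.10,4.65,17.46
Parafield,23.53,136.10,10.05,35.95
Paravic,25.98,93.54,6.12,22.40
PBA Gunyah,25.56,96.06,6.20,20.00
PBA Oura,25.87,77.13,4.79,18.05
PBA Pearl,26.03,84.67,5.42,20.11
PBA Percy,25.71,175.42,11.42,42.23
PBA Twilight,26.14,83.16,5.05,18.12
PBA Wharton,25.51,87.60,5.55,18.73
Santi,25.97,81.05,5.08,18.78
Snowpeak,25.58,101.93,6.95,25.09
Soupa,25.65,187.80,12.61,48.05
Sturt,26.16,153.58,9.66,45.74
SW Celine,25.95,93.74,6.07,23.42
Whero,22.59,162.20,12.70,34.60
White Brunswick,25.68,193.67,12.77,49.75
Wirrega,25.94,177.10,11.67,49.85
Yarrum,26.15,75.42,4.82,14.44
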