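compound,G01,G02,G03,G04,G05,G06,G07,G08,G09,G10,G11,G12,G13,G14
1-O-Vanilloyl-β-D-glucose,-,-,-,-,-,-,301.1 ± 31.9,122.1 ± 78.3,158.6 ± 14.0,60.1 ± 60.0,123.4 ± 1.3,126.4 ± 70.0,-,-
Vanillic acid,-,-,-,-,-,-,72.9 ± 9.9,40.7 ± 19.2,51.9 ± 2.9,53.3 ± 0.3,52.0 ± 1.7,53.7 ± 19.0,38.4 ± 4.9,43.3 ± 7.3
"2,5-Dihydrobenzoic acid",38.8 ± 0.4,122.0 ± 4.6,100.8 ± 8.7,43.5 ± 6.8,245.5 ± 17.3,171.3 ± 1.0,156.7 ± 5.5,135.4 ± 6.2,106.3 ± 25.5,102.9 ± 1.7,170.5 ± 5.8,155.8 ± 7.4,14.5 ± 0.6,16.1 ± 0.3
Gentisic acid 2-O-β-glucoside,-,-,4.6 ± 0.2,3.9 ± 0.7,32.2 ± 1.0,46.3 ± 3.8,32.3 ± 5.1,19.8 ± 0.1,19.0 ± 3.0,20.9 ± 1.6,27.4 ± 1.4,22.7 ± 0.2,0.4 ± 0.2,0.3 ± 0.3
Gentisic acid 5-O-β-glucoside,1.4 ± 0.1,3.2 ± 0.2,5.3 ± 0.3,3.8 ± 0.1,30.2 ± 0.8,67.3 ± 7.1,26.1 ± 2.2,14.3 ± 0.6,18.9 ± 1.9,20.6 ± 1.7,21.8 ± 1.2,17.6 ± 0.2,0.5 ± 0.1,0.3 ± 0.1
4-Hydroxybenzoic acid,0.2 ± 0.0,1.8 ± 0.1,7.7 ± 2.5,17.1 ± 0.9,48.5 ± 1.5,37.6 ± 4.8,28.2 ± 2.7,32.7 ± 0.2,33.6 ± 0.5,30.3 ± 2.6,45.7 ± 1.8,73.6 ± 3.1,8.7 ± 1.7,5.7 ± 0.6
4-Hydroxybenzaldehyde,16.4 ± 0.8,16.3 ± 0.8,36.9 ± 1.0,20.1 ± 1.9,20.8 ± 1.0,26.8 ± 1.0,22.6 ± 1.5,37.3 ± 2.2,12.1 ± 0.9,9.6 ± 0.1,48.9 ± 1.4,61.4 ± 4.3,5.9 ± 0.6,4.3 ± 0.4
Hydroxybenzoic-4-β-glucoside,-,-,-,-,9.4 ± 0.5,26.6 ± 0.9,5.0 ± 0.1,5.8 ± 0.3,4.2 ± 1.3,5.3 ± 0.9,3.9 ± 0.2,2.9 ± 0.1,-,-
Neochlorogenic acid,0.8 ± 0.2,2.2 ± 0.1,1.4 ± 0.5,0.2 ± 0.0,52.3 ± 0.6,22.5 ± 0.3,55.1 ± 6.4,62.8 ± 1.0,83.1 ± 3.2,59.6 ± 3.3,86.0 ± 3.7,81.1 ± 0.5,-,-
Chlorogenic acid,1.9 ± 0.2,3.6 ± 0.1,4.8 ± 0.7,3.5 ± 1.9,165.7 ± 19.1,85.4 ± 0.5,106.0 ± 8.4,131.5 ± 4.1,103.7 ± 15.7,100.0 ± 5.3,70.7 ± 3.8,71.5 ± 0.5,2.6 ± 0.1,2.5 ± 0.3
4-Caffeoylquinic acid,1.2 ± 0.1,2.2 ± 0.1,0.8 ± 0.4,0.2 ± 0.0,26.5 ± 0.8,15.1 ± 0.5,28.0 ± 2.5,34.4 ± 1.4,43.4 ± 3.2,40.4 ± 1.5,42.9 ± 1.1,44.7 ± 1.5,-,-
5-O-Feruloylquinic acid,14.8 ± 1.3,54.5 ± 1.7,124.4 ± 10.3,18.2 ± 5.8,333.5 ± 26.9,200.1 ± 2.6,186.2 ± 6.9,240.3 ± 11.4,102.4 ± 22.1,122.2 ± 2.5,163.9 ± 0.2,153.7 ± 2.8,6.2 ± 0.1,8.1 ± 0.4
trans-3-Feruloylquinic acid,-,-,88.8 ± 4.4,17.9 ± 1.9,44.3 ± 1.7,27.1 ± 0.3,87.4 ± 5.8,121.9 ± 2.5,11.8 ± 1.0,9.7 ± 0.6,94.5 ± 0.7,57.8 ± 25.9,3.5 ± 0.2,4.5 ± 0.2
Feruloylquinic acid isomer,9.2 ± 1.2,25.1 ± 0.1,-,-,169.5 ± 11.7,108.7 ± 1.7,11.7 ± 0.7,12.2 ± 0.2,79.8 ± 1.0,74.5 ± 2.7,9.3 ± 0.6,49.4 ± 10.0,-,-
Caffeic acid,1.7 ± 0.2,3.3 ± 0.1,8.1 ± 0.5,2.1 ± 1.7,17.8 ± 1.1,12.8 ± 0.2,11.5 ± 0.3,13.9 ± 1.4,35.8 ± 8.9,42.6 ± 0.7,24.2 ± 1.4,46.1 ± 3.4,5.8 ± 0.3,6.5 ± 0.5
Ferulic acid,14.3 ± 0.2,33.0 ± 0.1,42.2 ± 1.3,28.4 ± 0.8,57.9 ± 1.6,47.7 ± 3.8,40.6 ± 0.7,48.5 ± 0.7,40.3 ± 10.0,50.2 ± 0.6,31.1 ± 0.8,34.3 ± 0.6,6.7 ± 1.0,7.0 ± 1.1
p-Coumaric acid,63.9 ± 5.6,59.7 ± 0.9,120.6 ± 11.9,102.4 ± 17.3,63.8 ± 1.4,59.7 ± 11.0,74.2 ± 1.6,83.0 ± 2.5,30.8 ± 1.7,38.5 ± 1.1,37.4 ± 2.2,53.6 ± 1.6,21.4 ± 0.7,22.0 ± 1.3
Caffeoylquinic acid,3.2 ± 0.4,13.7 ± 0.6,24.1 ± 2.1,22.5 ± 5.0,38.3 ± 0.4,26.9 ± 0.8,37.2 ± 1.8,46.3 ± 3.2,15.5 ± 2.2,17.4 ± 0.2,27.6 ± 2.8,26.4 ± 2.8,6.5 ± 0.4,8.6 ± 0.8
Apigenin-8-C-glucoside,13.5 ± 0.5,32.9 ± 1.1,38.6 ± 1.0,27.8 ± 0.9,127.9 ± 10.0,70.6 ± 5.0,72.2 ± 1.5,80.0 ± 1.6,59.8 ± 2.5,56.6 ± 6.7,64.7 ± 3.5,52.7 ± 1.3,11.4 ± 1.0,12.0 ± 0.5
Isovitexin 2″-O-arabinoside,1.20 ± 0.1,4.3 ± 0.1,3.5 ± 0.2,3.7 ± 1.1,20.1 ± 1.9,27.7 ± 0.7,3.5 ± 0.3,2.0 ± 0.1,1.3 ± 0.1,1.5 ± 0.1,-,-,-,-
Isoschaftoside,17.07 ± 1.4,40.7 ± 2.6,44.1 ± 4.5,38.0 ± 7.0,4.7 ± 0.6,6.73 ± 0.1,55.4 ± 3.3,37.2 ± 1.1,22.3 ± 1.5,24.4 ± 0.5,15.1 ± 2.0,17.7 ± 0.2,7.3 ± 0.8,8.4 ± 0.4
Luteolin-6-C-glucoside,-,-,101.6 ± 6.5,56.9 ± 17.2,250.3 ± 42.1,221.0 ± 0.9,215.4 ± 20.9,290.1 ± 1.0,129.8 ± 17.5,137.5 ± 2.9,174.5 ± 22.7,168.6 ± 1.0,37.8 ± 4.4,40.3 ± 1.5
Luteolin-8-C-glucoside,-,-,-,-,42.9 ± 4.4,9.7 ± 0.5,22.3 ± 2.1,29.2 ± 1.8,13.9 ± 1.4,3.4 ± 0.1,7.8 ± 1.4,6.6 ± 0.4,12.4 ± 0.4,12.8 ± 1.6
Apigenin 7-O-neohesperidoside,4.1 ± 0.6,9.0 ± 0.3,2.6 ± 0.4,5.64 ± 1.2,28.9 ± 1.5,17.6 ± 1.1,14.3 ± 0.9,21.9 ± 0.2,27.0 ± 3.3,22.6 ± 0.2,11.3 ± 0.5,5.5 ± 0.2,-,-
Tricin,3.8 ± 0.1,7.3 ± 0.6,0.01 ± 0.0,0.01 ± 0.0,8.7 ± 0.5,9.7 ± 0.4,14.4 ± 1.0,14.3 ± 0.9,33.1 ± 1.1,27.9 ± 1.0,9.7 ± 0.5,9.9 ± 0.6,4.8 ± 0.4,5.1 ± 0.5
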