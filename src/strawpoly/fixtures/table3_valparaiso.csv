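compound,V01,V02,V03,V04,V05,V06,V07,V08,V09,V10,V11,V12,V13,V14
1-O-Vanilloyl-β-D-glucose,-,-,-,-,-,-,36.2 ± 0.4,21.3 ± 10.6,114.3 ± 14.5,11.4 ± 2.6,74.1 ± 0.7,1.2 ± 0.1,-,-
Vanillic acid,-,-,-,-,-,-,21.2 ± 3.5,11.7 ± 1.8,78.6 ± 4.1,4.2 ± 1.3,114.4 ± 5.5,2.5 ± 0.8,50.7 ± 2.3,8.8 ± 0.1
"2,5-Dihydrobenzoic acid",16.0 ± 0.2,18.1 ± 0.5,142.4 ± 2.3,62.6 ± 1.8,125.7 ± 13.0,145.8 ± 12.1,17.6 ± 3.2,10.5 ± 1.2,10.0 ± 0.7,29.5 ± 1.7,53.6 ± 0.5,57.6 ± 0.8,19.9 ± 0.3,17.8 ± 0.3
Gentisic acid 2-O-β-glucoside,-,-,19.3 ± 0.5,11.2 ± 0.2,20.8 ± 1.7,24.8 ± 1.3,-,-,-,5.9 ± 0.5,-,2.6 ± 0.2,0.6 ± 0.0,-
Gentisic acid 5-O-β-glucoside,-,-,14.2 ± 0.1,6.9 ± 0.3,14.5 ± 0.7,20.4 ± 0.0,-,-,-,5.9 ± 0.7,-,2.6 ± 0.2,0.4 ± 0.3,-
4-Hydroxybenzoic acid,1.4 ± 0.5,0.5 ± 0.1,43.6 ± 1.6,22.2 ± 1.1,77.8 ± 0.5,43.8 ± 1.0,3.0 ± 0.4,1.7 ± 1.7,1.3 ± 0.1,18.2 ± 1.6,49.8 ± 0.2,26.7 ± 4.2,12.9 ± 0.2,11.5 ± 0.2
"3,4-Dihydroxybenzaldehyde",1.8 ± 0.0,3.9 ± 1.0,5.1 ± 0.2,2.3 ± 0.6,2.7 ± 0.2,18.3 ± 0.5,-,-,-,-,1.7 ± 0.3,-,-,-
4-Hydroxybenzaldehyde,11.2 ± 0.8,29.8 ± 0.7,19.2 ± 0.1,35.3 ± 1.1,17.8 ± 1.0,38.2 ± 1.1,24.9 ± 0.1,22.6 ± 0.6,9.4 ± 1.0,9.6 ± 0.7,23.5 ± 0.9,24.5 ± 0.8,8.4 ± 0.1,8.2 ± 0.1
Neochlorogenic acid,1.0 ± 0.2,1.1 ± 0.3,26.4 ± 1.5,7.2 ± 1.2,103.5 ± 12.0,106.7 ± 9.0,-,-,-,12.1 ± 0.0,28.5 ± 2.5,4.1 ± 0.8,-,-
Chlorogenic acid,2.0 ± 0.2,1.1 ± 0.3,68.9 ± 3.2,21.6 ± 3.3,255.1 ± 4.4,272.8 ± 6.0,2.5 ± 0.7,2.4 ± 0.1,3.2 ± 0.4,8.5 ± 7.1,42.9 ± 2.4,12.5 ± 0.3,3.2 ± 0.1,3.2 ± 0.1
4-Caffeoylquinic acid,1.3 ± 0.1,1.2 ± 0.1,14.1 ± 1.1,5.9 ± 0.8,60.3 ± 3.0,51.3 ± 2.6,-,-,-,8.8 ± 0.0,20.7 ± 1.2,3.9 ± 0.2,-,-
5-O-Feruloylquinic acid,8.2 ± 1.3,13.5 ± 1.0,263.2 ± 1.3,105.3 ± 2.9,211.5 ± 20.0,391.5 ± 8.1,4.5 ± 1.5,2.0 ± 0.2,4.9 ± 0.3,71.7 ± 2.9,149.6 ± 8.3,46.6 ± 5.7,17.5 ± 0.2,14.5 ± 0.1
trans-3-Feruloylquinic acid,-,-,16.8 ± 0.4,7.6 ± 0.4,12.9 ± 1.9,65.5 ± 4.7,4.7 ± 0.6,2.4 ± 0.0,4.4 ± 0.3,5.3 ± 0.7,48.1 ± 10.0,12.6 ± 1.0,10.4 ± 0.1,8.3 ± 0.0
Feruloylquinic acid isomer,6.0 ± 1.1,10.6 ± 1.0,118.5 ± 1.3,86.8 ± 0.5,100.4 ± 9.9,204.1 ± 12.6,-,-,-,46.5 ± 2.9,-,28.2 ± 1.1,-,-
Caffeic acid,1.9 ± 0.2,1.4 ± 0.3,14.1 ± 0.7,5.6 ± 0.2,53.6 ± 12.0,25.8 ± 1.4,3.3 ± 0.7,3.7 ± 0.3,2.1 ± 0.2,4.1 ± 0.2,50.3 ± 4.3,14.9 ± 0.8,4.3 ± 0.1,4.1 ± 0.0
Ferulic acid,14.2 ± 1.0,13.2 ± 0.9,52.5 ± 0.5,46.4 ± 0.1,40.4 ± 1.7,56.8 ± 2.2,17.1 ± 0.6,16.2 ± 0.4,18.3 ± 0.7,27.7 ± 0.5,20.7 ± 0.1,21.7 ± 0.4,-,-
p-Coumaric acid,71.3 ± 5.6,100.8 ± 5.8,75.6 ± 1.1,125.3 ± 11.5,59.8 ± 1.7,76.6 ± 2.6,95.9 ± 5.6,106.3 ± 2.7,37.2 ± 2.7,29.1 ± 0.4,40.8 ± 0.4,41.3 ± 0.9,20.5 ± 0.2,23.5 ± 0.2
Caffeoylquinic acid,2.7 ± 0.4,2.8 ± 0.3,49.9 ± 1.8,53.7 ± 2.5,43.3 ± 5.9,58.9 ± 0.4,4.9 ± 0.7,3.1 ± 0.4,1.8 ± 0.1,14.5 ± 0.5,23.2 ± 1.7,16.9 ± 1.4,6.3 ± 0.1,6.0 ± 0.0
"4,5-Dicaffeoylquinic acid",-,-,-,-,41.7 ± 2.9,11.2 ± 0.6,-,-,-,4.9 ± 0.2,-,2.2 ± 0.2,-,-
Apigenin-8-C-glucoside,9.1 ± 0.2,7.0 ± 0.3,93.2 ± 0.6,35.5 ± 1.5,103.8 ± 2.7,124.2 ± 2.0,11.2 ± 0.3,8.8 ± 0.2,10.7 ± 0.2,32.6 ± 0.6,49.3 ± 0.5,32.3 ± 0.5,8.3 ± 0.6,9.7 ± 0.1
Isovitexin 2″-O-arabinoside,0.8 ± 0.1,0.4 ± 0.0,7.0 ± 0.2,6.9 ± 0.9,51.5 ± 1.1,49.2 ± 2.0,0.7 ± 0.1,0.9 ± 0.1,1.5 ± 0.1,3.3 ± 0.1,-,-,-,-
Isoschaftoside,12.0 ± 1.0,9.3 ± 0.7,73.6 ± 2.2,63.6 ± 2.7,7.9 ± 0.4,6.7 ± 0.1,9.1 ± 0.4,11.2 ± 0.1,17.9 ± 1.0,37.7 ± 0.7,33.0 ± 0.2,33.4 ± 0.7,14.8 ± 0.2,17.5 ± 0.7
Apigenin-6-C-glucosyl-8-C-arabinoside,2.4 ± 1.0,3.3 ± 1.1,13.7 ± 1.1,7.5 ± 1.2,14.5 ± 0.3,20.3 ± 0.3,-,-,2.1 ± 0.1,3.9 ± 0.2,7.9 ± 0.5,11.4 ± 0.2,3.7 ± 0.0,4.1 ± 0.1
Luteolin-6-C-glucoside,-,-,188.7 ± 0.8,139.5 ± 3.5,244.9 ± 3.7,397.8 ± 19.2,28.2 ± 6.3,22.1 ± 5.4,19.9 ± 0.1,47.8 ± 1.1,213.6 ± 3.9,112.4 ± 2.9,24.3 ± 0.4,21.9 ± 1.5
Apigenin 7-O-neohesperidoside,0.6 ± 0.3,0.6 ± 0.2,9.5 ± 0.3,11.9 ± 1.2,13.6 ± 0.1,38.3 ± 0.5,-,-,0.8 ± 0.0,1.3 ± 0.1,7.5 ± 0.4,1.4 ± 0.1,-,-
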