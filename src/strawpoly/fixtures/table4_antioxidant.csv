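sample_id,area,collection_date,variety,infection_class,harvest_number,abts,dpph
G01,Guariba,2020-06-04,CTC9001,high,1,3.4 ± 0.0,8.8 ± 1.4
G02,Guariba,2020-06-04,CTC9001,low,1,2.3 ± 0.0,4.7 ± 0.0
G03,Guariba,2020-07-03,CTC9001,high,1,1.8 ± 0.1,5.3 ± 0.5
G04,Guariba,2020-07-03,RB966928,low,7,2.2 ± 1.5,6.8 ± 4.1
G05,Guariba,2020-07-24,RB966928,high,1,ND,ND
G06,Guariba,2020-07-24,RB966928,low,1,ND,ND
G07,Guariba,2020-08-08,RB985476,high,1,1.5 ± 0.1,1.4 ± 0.2
G08,Guariba,2020-08-08,CTC4,low,3,1.5 ± 0.1,1.5 ± 0.3
G09,Guariba,2020-09-22,CU7870,high,4,1.2 ± 0.0,1.1 ± 0.0
G10,Guariba,2020-09-22,CU7870,low,4,1.5 ± 0.1,2.1 ± 0.0
G11,Guariba,2020-10-14,RB985476,high,2,0.9 ± 0.0,1.0 ± 0.1
G12,Guariba,2020-10-14,SP803280,low,4,1.0 ± 0.0,1.2 ± 0.1
G13,Guariba,2020-11-16,CU7870,high,1,ND,ND
G14,Guariba,2020-11-16,CU7870,low,1,ND,ND
V01,Valparaiso,2020-06-04,RB966928,high,1,3.3 ± 0.0,6.9 ± 0.6
V02,Valparaiso,2020-06-04,CTC9001,low,1,3.6 ± 0.0,9.1 ± 1.1
V03,Valparaiso,2020-07-03,CTC15,high,7,1.4 ± 0.1,3.1 ± 1.0
V04,Valparaiso,2020-07-03,CTC15,low,5,1.7 ± 0.1,4.6 ± 0.2
V05,Valparaiso,2020-07-24,CU7870,high,2,ND,ND
V06,Valparaiso,2020-07-24,CTC4,low,1,ND,ND
V07,Valparaiso,2020-08-08,RB966928,high,3,2.9 ± 0.0,3.8 ± 0.2
V08,Valparaiso,2020-08-08,CU7870,low,4,2.9 ± 0.1,4.0 ± 0.5
V09,Valparaiso,2020-09-22,CU7870,high,5,1.2 ± 0.1,1.2 ± 0.2
V10,Valparaiso,2020-09-22,CU0618,low,3,1.4 ± 0.0,1.4 ± 0.0
V11,Valparaiso,2020-10-14,CTC15,high,6,2.0 ± 0.0,5.0 ± 0.8
V12,Valparaiso,2020-10-14,CTC15,low,5,1.3 ± 0.1,2.4 ± 0.5
V13,Valparaiso,2020-11-16,CU7870,high,2,ND,ND
V14,Valparaiso,2020-11-16,CTC4,low,1,ND,ND
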