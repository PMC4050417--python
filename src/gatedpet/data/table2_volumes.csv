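patient,lesion,ptv_cc,ptvg_cc,bitv_cc,btv_cc,ctv_cc,liver_cc
1,1,30.4,24.7,9.9,5.0,5.4,1671
1,2,9.6,6.3,1.7,0.7,0.8,1671
2,1,29.8,41.8,21.6,9.4,5.6,1485
2,2,34.6,26.4,12.6,7.9,7.9,1485
3,1,12.0,5.8,1.4,0.7,1.1,1530
4,1,113.0,73.2,39.0,34.2,42.0,1293
4,2,52.8,34.4,17.3,14.9,14.6,1293
5,1,49.1,24.8,11.6,13.5,13.5,1758
5,2,23.2,12.4,4.7,4.5,4.5,1758
5,3,25.1,14.1,5.4,5.0,5.0,1758
6,1,20.0,10.0,3.5,3.2,3.4,2230
6,2,16.4,8.5,2.7,1.8,2.2,2230
7,1,29.3,13.6,5.4,4.8,5.3,1502
8,1,16.3,12.1,4.4,2.4,2.4,1206
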