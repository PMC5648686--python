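district_id,rotation,feeding,area_lichen,area_arboreal,arboreal_avail,z_1995,z_2008,growth_rel,hm_reduction_pct,infra_pct
1,NO,12,78780,1836,6,33,129,0.49,20,3.4
2,NO,12,58672,1830,6,65,76,0.57,20,4.7
3,YES,12,16542,10169,6,801,244,0.72,40,5.2
4,YES,75,21537,17051,6,1606,409,0.74,20,9.8
5,YES,12,11064,20168,6,1446,348,0.85,60,5.4
6,NO,12,12043,15976,6,1877,464,0.91,40,2.6
7,NO,12,72330,43599,9,470,313,0.78,20,14.8
8,NO,12,67088,35238,9,1021,603,0.77,20,7.5
9,YES,12,32940,26491,9,594,421,0.66,0,2.5
10,YES,12,23328,23860,6,431,252,0.73,20,3.8
11,NO,12,82343,16444,6,409,128,0.62,0,4.8
12,NO,12,113197,3332,6,364,246,0.50,0,4.8
13,NO,75,66937,39235,12,187,184,0.82,0,27.2
14,YES,37,9841,17016,12,501,324,0.70,0,10
15,NO,200,42062,41494,12,332,202,0.77,0,10.6
16,YES,125,12546,24511,12,365,194,0.76,0,10.6
17,NO,200,38345,34047,12,421,102,0.75,0,13
18,YES,75,57930,56927,9,600,820,0.78,0,4.3
19,NO,75,131049,83908,12,563,366,0.75,0,4.8
20,NO,12,44281,28528,12,237,250,0.72,0,8.4
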