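rank,city,sum_dn,odr
1,Suzhou,373261,18.076
2,Tianjin,349408,17.923
3,Beijing,348231,17.915
4,Shanghai,334746,17.819
5,Chongqing,300330,17.538
6,Harbin,265159,17.182
7,Guangzhou,256275,17.078
8,Tangshan,254191,17.053
9,Weifang,249205,16.990
10,Ningbo,232518,16.765
11,Nantong,230225,16.731
12,Chengdu,223101,16.624
13,Yantai,218269,16.548
14,Qingdao,214348,16.483
15,Linyi,211939,16.443
16,Quanzhou,210609,16.420
17,Hangzhou,208367,16.381
18,Cangzhou,200063,16.230
19,Changchun,197844,16.188
20,Baoding,189983,16.032
21,Yancheng,188884,16.009
22,Ordos,187564,15.981
23,Wuxi,186016,15.948
24,Yulin,180977,15.838
25,Nanjing,180621,15.830
26,Zhengzhou,176195,15.728
27,Shijiazhuang,174421,15.686
28,Jinan,173470,15.663
29,Shenyang,170688,15.595
30,Handan,170627,15.593
31,Jining,170199,15.582
32,Wuhan,170083,15.580
33,Foshan,169524,15.566
34,Huizhou,167721,15.520
35,Xuzhou,166657,15.492
36,Dalian,157692,15.249
37,Fuzhou,156327,15.210
38,Kunming,155533,15.187
39,Nanyang,152235,15.089
40,Langfang,150066,15.022
41,Daqing,149761,15.013
42,Suihua,146411,14.907
43,Wenzhou,145549,14.879
44,Zhangzhou,145227,14.868
45,Jiaxing,145137,14.865
46,Xi'an,144576,14.847
47,Dongguan,140280,14.702
48,Yan'an,140273,14.701
49,Jinhua,139724,14.682
50,Taizhou (Zhejiang),139068,14.659
51,Qiqihar,138330,14.633
52,Xingtai,136448,14.566
53,Yangzhou,136258,14.559
54,Binzhou,136179,14.556
55,Taizhou (Jiangsu),135832,14.543
56,Hulunbeir,135027,14.513
57,Luliang,133380,14.452
58,Changzhou,133260,14.447
59,Jiangmen,132327,14.412
60,Hefei,132237,14.409
61,Heze,131710,14.388
62,Dezhou,130769,14.352
63,Shaoxing,126333,14.174
64,Changsha,123222,14.043
65,Dongying,115762,13.706
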