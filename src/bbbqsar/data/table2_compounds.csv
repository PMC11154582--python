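compound_id,class,mw,nrb,hbd,hba,tpsa,alpha,log_bb,log_kw_iam,provenance
1,I,186.21,1,0,4,33.95,21.80,-0.033,0.10,
2,I,200.24,1,0,4,33.95,23.56,-0.159,0.41,
3,I,216.24,2,0,5,43.18,24.11,-0.068,0.10,
4,I,220.66,1,0,4,33.95,23.63,-0.128,0.64,
5,I,255.10,1,0,4,33.95,25.45,0.209,1.18,
6,II,292.34,4,0,5,43.18,34.13,0.292,0.11,
7,II,356.81,5,0,6,52.41,38.26,0.340,0.06,
8,II,340.81,4,0,5,43.18,37.71,0.571,0.09,
9,II,354.83,4,0,5,43.18,39.47,0.763,1.95,
10,II,361.22,4,0,5,43.18,37.78,0.476,1.86,
11,II,375.25,4,0,5,43.18,39.54,0.668,2.14,
12,II,395.67,4,0,5,43.18,39.61,0.626,2.25,
13,II,430.11,4,0,5,43.18,41.43,0.772,2.91,
14,II,430.11,4,0,5,43.18,41.43,0.758,2.55,
15,III,282.22,2,0,5,48.27,25.85,0.102,0.94,a
16,III,296.25,2,0,5,48.27,27.61,0.290,0.76,a
17,III,296.25,2,0,5,48.27,27.61,0.290,1.25,a
18,III,312.25,3,0,6,57.50,28.16,0.063,0.67,a
19,III,316.67,2,0,5,48.27,27.68,0.211,0.88,a
20,III,316.67,2,0,5,48.27,27.68,0.264,1.66,a
21,III,316.67,2,0,5,48.27,27.68,0.194,1.58,a
22,III,351.11,2,0,5,48.27,29.50,0.345,2.29,a
23,IV,242.28,2,0,5,48.27,27.55,0.117,0.55,b
24,IV,256.30,2,0,5,48.27,29.30,0.305,1.00,b
25,IV,276.72,2,0,5,48.27,29.37,0.226,0.80,b
26,IV,276.72,2,0,5,48.27,29.37,0.270,0.84,b
27,IV,276.72,2,0,5,48.27,29.37,0.209,1.24,b
28,IV,311.17,2,0,5,48.27,31.20,0.360,1.85,b
29,V,256.30,2,0,5,48.27,29.30,0.230,0.76,a
30,V,270.33,2,0,5,48.27,31.06,0.423,1.05,a
31,V,290.75,2,0,5,48.27,31.13,0.339,0.65,a
32,V,290.75,2,0,5,48.27,31.13,0.384,1.49,a
33,V,290.75,2,0,5,48.27,31.13,0.328,1.39,a
34,V,325.19,2,0,5,48.27,32.95,0.473,1.67,a
35,VI,286.29,4,0,7,74.57,30.27,-0.243,0.48,a
36,VI,300.31,4,0,7,74.57,32.02,-0.051,1.93,a
37,VI,320.73,4,0,7,74.57,32.09,-0.090,1.73,a
38,VI,320.73,4,0,7,74.57,32.09,-0.151,1.12,a
39,VI,355.18,4,0,7,74.57,33.91,0.000,3.36,a
40,VII,286.29,4,0,7,74.57,30.27,-0.243,0.81,b
41,VII,300.31,4,0,7,74.57,32.02,-0.051,1.33,b
42,VII,316.31,5,0,8,83.80,32.57,-0.293,0.81,b
43,VII,330.34,6,0,8,83.80,34.40,-0.167,1.42,b
44,VII,320.73,4,0,7,74.57,32.09,-0.151,1.82,b
45,VIII,300.31,5,0,7,74.57,32.09,-0.132,1.21,b
46,VIII,314.34,5,0,7,74.57,33.85,0.055,1.70,b
47,VIII,330.34,6,0,8,83.80,34.40,-0.164,0.91,b
48,VIII,334.76,5,0,7,74.57,33.92,0.029,2.05,b
49,VIII,334.76,5,0,7,74.57,33.92,-0.033,2.11,b
50,VIII,369.20,5,0,7,74.57,35.74,0.117,2.42,b
51,IX,274.28,2,3,8,103.39,28.32,-1.002,-0.14,c
52,IX,288.31,2,3,8,103.39,30.07,-0.815,0.16,c
53,IX,304.30,3,3,9,112.62,30.62,-1.050,-0.10,c
54,IX,308.72,2,3,8,103.39,30.14,-0.845,0.41,c
55,IX,343.17,2,3,8,103.39,31.96,-0.764,0.69,c
56,X,288.26,4,3,9,112.62,28.65,-1.272,0.40,
57,X,302.29,4,3,9,112.62,30.41,-1.084,0.13,
58,X,318.29,5,3,10,121.85,30.96,-1.315,-0.27,
59,X,332.31,6,3,10,121.85,32.79,-1.189,0.06,
60,X,322.71,4,3,9,112.62,30.48,-1.173,0.32,
61,XI,280.28,2,0,6,61.41,30.82,0.038,1.29,b
62,XI,294.31,2,0,6,61.41,32.57,0.225,0.96,b
63,XI,294.31,2,0,6,61.41,32.57,0.225,1.69,b
64,XI,308.33,2,0,6,61.41,34.33,0.417,1.42,b
65,XI,310.31,3,0,7,70.64,33.12,0.006,1.11,b
66,XI,310.31,3,0,7,70.64,33.12,0.003,1.19,b
67,XI,314.73,2,0,6,61.41,32.64,0.141,1.27,b
68,XI,314.73,2,0,6,61.41,32.64,0.194,2.08,b
69,XI,314.73,2,0,6,61.41,32.64,0.130,2.02,b
70,XI,349.17,2,0,6,61.41,34.47,0.280,3.23,b
71,XI,349.17,2,0,6,61.41,34.47,0.297,1.70,b
72,XII,300.38,2,0,5,73.57,33.36,0.383,1.64,
73,XII,314.41,2,0,5,73.57,35.12,0.562,1.54,
74,XII,314.41,2,0,5,73.57,35.12,0.562,1.94,
75,XII,328.43,2,0,5,73.57,36.87,0.754,1.17,
76,XII,330.41,3,0,6,82.80,35.67,0.351,1.50,
77,XII,334.82,2,0,5,73.57,35.19,0.483,1.75,
78,XII,334.82,2,0,5,73.57,35.19,0.536,2.26,
79,XII,334.82,2,0,5,73.57,35.19,0.475,1.53,
80,XII,369.27,2,0,5,73.57,37.01,0.625,2.68,
81,XIII,290.32,2,0,5,48.27,33.92,0.227,1.91,b
82,XIII,304.35,2,0,5,48.27,35.68,0.407,1.53,b
83,XIII,304.35,2,0,5,48.27,35.68,0.407,2.26,b
84,XIII,304.35,2,0,5,48.27,35.68,0.407,2.22,b
85,XIII,320.35,3,0,6,57.50,36.23,0.188,1.47,b
86,XIII,320.35,3,0,6,57.50,36.23,0.172,1.71,b
87,XIII,334.37,4,0,6,57.50,38.05,0.298,2.14,b
88,XIII,318.37,2,0,5,48.27,37.43,0.594,1.85,b
89,XIII,324.76,2,0,5,48.27,35.75,0.331,1.73,b
90,XIII,324.76,2,0,5,48.27,35.75,0.376,2.64,b
91,XIII,324.76,2,0,5,48.27,35.75,0.319,2.57,b
92,XIII,359.21,2,0,5,48.27,37.57,0.465,3.26,b
93,XIV,335.32,3,0,8,97.10,36.17,-0.059,1.92,
94,XIV,349.34,3,0,8,97.10,37.92,0.133,2.52,
95,XIV,349.34,3,0,8,97.10,37.92,0.133,1.83,
96,XIV,365.34,4,0,9,106.33,38.47,-0.086,1.78,
97,XIV,363.37,3,0,8,97.10,39.67,0.320,1.78,
98,XIV,369.76,3,0,8,97.10,37.99,0.049,2.16,
99,XIV,369.76,3,0,8,97.10,37.99,0.102,2.02,
100,XIV,369.76,3,0,8,97.10,37.99,0.038,2.52,
101,XIV,404.21,3,0,8,97.10,39.81,0.183,3.22,
102,XV,304.35,3,0,5,48.27,35.75,0.341,3.26,b
103,XV,338.79,3,0,5,48.27,37.57,0.459,2.34,b
104,XV,338.79,3,0,5,48.27,37.57,0.459,2.48,b
105,XV,338.79,3,0,5,48.27,37.57,0.459,2.39,b
106,XV,318.37,3,0,5,48.27,37.50,0.524,2.15,b
107,XV,332.40,3,0,5,48.27,39.26,0.712,2.51,b
108,XV,332.40,3,0,5,48.27,39.26,0.712,2.59,b
109,XV,352.82,3,0,5,48.27,39.33,0.635,2.65,b
110,XV,352.82,3,0,5,48.27,39.33,0.635,2.78,b
111,XV,352.82,3,0,5,48.27,39.33,0.635,2.81,b
112,XV,348.40,5,0,6,57.50,39.88,0.424,2.11,b
113,XV,362.43,5,0,6,57.50,41.63,0.602,2.43,b
114,XV,382.84,5,0,6,57.50,41.70,0.526,2.51,b
115,XV,382.84,5,0,6,57.50,41.70,0.526,2.73,b
116,XV,382.84,5,0,6,57.50,41.70,0.526,2.72,b
117,XV,352.82,3,0,5,48.27,39.33,0.635,2.02,b
118,XV,338.79,3,0,5,48.27,37.57,0.440,2.52,b
119,XV,373.24,3,0,5,48.27,39.40,0.551,3.22,b
120,XV,373.24,3,0,5,48.27,39.40,0.551,3.15,b
121,XV,373.24,3,0,5,48.27,39.40,0.551,3.17,b
122,XVI,318.37,4,0,5,48.27,37.58,0.459,2.07,b
123,XVI,332.40,4,0,5,48.27,39.33,0.651,2.41,b
124,XVI,352.82,4,0,5,48.27,39.40,0.567,1.81,b
125,XVI,352.82,4,0,5,48.27,39.40,0.551,2.68,b
126,XVI,387.26,4,0,5,48.27,41.22,0.701,3.40,b
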