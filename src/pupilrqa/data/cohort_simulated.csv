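age,ess,entropy,det_pct,pct_change
24,1,0.76,33.9,-2.02
24,7,0.91,51.04,-1.94
24,11,0.86,43.69,-1.37
24,9,0.9,41.85,-1.37
24,10,0.84,45.84,-3.04
24,6,0.95,38.26,-3.55
24,4,0.97,49.38,-1.37
24,5,0.93,41.8,-3.42
24,8,0.89,44.1,-2.01
24,5,1.04,50.81,-2.01
24,9,0.84,41.36,-1.92
24,3,0.92,38.32,-3.42
24,6,0.99,50.99,-1.37
24,14,0.81,39.87,-3.47
24,4,0.83,35.69,-3.44
24,3,0.77,36.14,-2.54
24,14,0.97,51.16,-2.49
24,12,0.97,57.02,-1.98
24,5,1.0,56.28,-1.37
24,5,1.03,56.53,0.2
24,13,1.0,51.29,-2.28
24,5,1.0,50.54,1.71
25,5,0.87,41.7,-1.87
25,14,1.08,57.34,-2.48
25,14,0.83,41.76,-1.42
25,8,0.9,37.86,-2.92
26,3,0.93,38.25,-1.38
27,9,0.97,54.93,-2.01
27,4,0.74,30.17,-1.67
27,2,0.88,49.28,1.39
27,6,0.81,44.77,-1.04
27,4,0.86,36.67,-2.27
27,3,0.75,33.77,0.74
27,5,0.88,39.46,0.31
27,3,1.0,41.9,-0.43
27,3,0.83,37.81,0.71
27,6,0.83,37.51,-3.07
28,3,0.86,45.83,2.08
28,7,0.95,43.95,-1.75
28,3,0.93,38.87,0.08
28,5,0.84,38.25,1.05
28,3,0.88,39.49,2.02
28,3,0.67,34.75,-0.67
28,5,0.83,28.51,-2.04
28,3,0.9,45.54,1.56
28,8,0.87,38.23,-2.39
28,7,0.89,38.19,0.03
29,3,0.68,25.23,-1.04
29,9,0.88,45.97,0.19
29,12,1.0,50.96,1.7
29,5,0.83,31.97,-1.37
29,5,1.0,51.3,0.29
29,6,0.96,37.97,-0.4
29,4,0.89,37.76,-1.75
29,6,0.91,43.87,-1.37
29,7,0.83,41.42,-3.45
29,3,0.88,42.35,0.42
29,3,0.91,39.35,-2.02
29,7,0.83,42.78,1.84
29,5,0.87,38.07,0.48
30,4,0.86,37.73,0.76
31,6,0.83,36.6,-0.39
31,14,0.97,56.78,2.23
32,9,0.94,45.02,-0.39
32,14,0.84,45.25,-1.55
34,8,0.96,45.95,-0.39
36,4,0.85,37.75,-3.36
41,13,0.86,51.06,0.3
41,6,0.83,35.96,-1.37
41,5,0.87,43.81,1.34
42,2,0.9,38.3,2.15
43,6,0.89,46.47,1.52
46,6,0.94,51.45,1.63
46,3,0.68,37.74,1.39
46,3,1.0,45.27,0.06
46,7,1.0,52.01,0.31
46,14,1.03,56.75,1.93
46,14,1.0,52.63,-1.47
46,6,0.89,50.6,1.42
46,14,0.83,37.84,-1.75
46,5,1.0,54.86,-1.64
47,3,0.92,38.32,0.33
47,8,0.9,56.6,1.76
48,4,0.89,46.61,1.42
49,3,0.83,37.95,1.41
49,9,0.95,45.01,-2.25
49,9,0.83,40.07,0.47
50,3,0.99,38.08,-2.01
50,3,0.84,31.53,0.84
50,7,1.0,56.82,1.96
51,7,0.88,45.02,2.03
51,13,0.97,38.15,1.47
51,7,0.73,37.41,2.03
52,3,0.89,44.98,1.96
53,8,1.08,56.66,2.05
56,14,1.05,57.08,1.15
56,7,0.96,41.81,-0.09
60,5,0.92,42.09,-1.57
61,5,1.01,44.96,1.08
63,7,1.02,57.21,2.28
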