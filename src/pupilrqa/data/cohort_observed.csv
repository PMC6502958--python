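age,ess,entropy,det_pct,pct_change
24,3,1.08,52.34,-0.38
24,5,0.97,49.64,0.85
24,5,0.96,56.69,3.97
24,6,1.0,57.39,-2.36
24,13,1.03,46.94,-1.69
24,14,0.9,48.86,-2.0
25,6,0.86,37.91,-1.57
25,14,0.92,43.09,0.3
27,2,0.84,38.14,1.94
27,7,0.86,50.49,0.74
27,9,1.0,37.73,-3.35
28,3,0.89,41.85,-1.37
28,4,0.83,41.29,0.19
29,5,0.87,42.43,1.72
29,10,0.83,37.35,-1.37
29,13,0.97,56.99,1.39
31,5,0.72,29.79,1.43
33,8,0.83,44.9,-2.02
46,7,0.88,39.78,-2.6
46,9,0.99,46.22,-0.4
49,6,0.77,45.12,1.16
50,3,0.9,38.35,-3.46
51,4,0.95,35.6,0.33
56,7,1.0,51.47,2.34
62,14,0.94,56.19,2.07
63,8,1.04,50.69,-0.08
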