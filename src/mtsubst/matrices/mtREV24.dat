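23.18
26.95 17.67
59.93 1.9 9.77
120.71 13.9 96.49 25.46
8.36 141.88 6.37 54.31 387.86
480.72 1.9 6.48 195.06 13.24 1.9
103.33 220.99 1.9 23.03 165.23 1.9 15.58
141.4 1.9 4.69 23.64 6.04 2.08 21.95 1.9
7.64 794.38 58.94 173.56 63.05 53.3 496.13 27.1 15.16
608.7 65.41 15.2 73.31 494.39 238.46 10.68 191.36 1.9 1.9
55.28 583.55 56.77 113.99 4.34 1.9 2.31 1.9 4.98 13.43 69.02
28.01 19.86 21.21 1.9 75.24 1.9 30.71 141.49 62.73 25.65 1.9 6.18
70.8 31.26 277.05 179.97 33.6 254.77 1.9 313.56 6.75 582.4 8.34 39.7 465.58
47.37 19.11 137.29 54.11 94.93 1.9 38.82 19 28.28 49.12 3.31 1.9 313.86 1.9
2.67 12.83 54.71 14.82 1.9 13.12 21.14 1.9 5.98 2.41 22.73 1.9 1.9 1.9 125.93
11.17 10.92 3.21 2.53 12.26 11.49 127.67 11.97 48.16 60.97 77.46 44.78 7.08 670.14 1.9 329.09
19.57 517.98 84.67 20.63 47.7 368.43 1.9 25.01 1222.94 14.88 537.53 216.06 40.1 73.61 126.4 32.44 44.15
91.67 91.37 6.44 50.1 105.79 136.33 24 51.17 1.9 90.82 18.84 111.16 528.17 21.71 39.96 387.54 17.31 64.29
33.85 7.84 465.58 6.35 169.9 128.22 4.21 16.21 8.23 597.21 38.58 64.92 1.9 9.99 38.73 204.54 26.25 5.37 1.9

0.072 0.019 0.039 0.019 0.006 0.025 0.024 0.056 0.028 0.088 0.169 0.023 0.054 0.061 0.054 0.072 0.086 0.029 0.033 0.043

# A R N D C Q E G H I L K M F P S T W Y V
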