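0.2
0.2 1
254 0.2 0.2
200 0.2 26 4
0.2 121 13 49 673
244 0.2 1 340 0.2 4
36 154 0.2 0.2 41 2 2
209 5 5 0.2 3 0.2 0.2 4
0.2 500 98 262 183 121 180 21 13
467 79 20 17 398 166 8 251 23 11
0.2 862 12 0.2 7 1 2 0.2 0.2 0.2 44
0.2 0.2 0.2 0.2 0.2 0.2 81 12 63 79 0.2 312
184 0.2 664 183 22 72 350 262 3 314 11 16 349
67 0.2 39 52 44 7 87 0.2 44 15 7 2 106 0.2
0.2 8 31 43 11 8 14 0.2 3 1 0.2 56 1 0.2 226
0.2 2 9 3 0.2 6 0.2 0.2 14 1 11 19 0.2 191 0.2 515
3 515 118 0.2 7 204 0.2 12 1855 4 885 263 12 8 48 21 20
85 106 11 17 144 70 16 117 26 322 5 112 289 71 71 281 15 36
14 54 792 52 87 47 0.2 18 32 660 2 30 61 0.2 46 544 38 0.2 2

0.054116 0.018227 0.039903 0.02016 0.009709 0.018781 0.024289 0.068183 0.024518 0.092638 0.148658 0.021718 0.061453 0.088668 0.041826 0.09103 0.049194 0.029786 0.039443 0.0577

# A R N D C Q E G H I L K M F P S T W Y V
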