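3.3
1.7 16.1
272.5 7.3 17.1
289.3 2.3 33.2 15.6
0.2 136.5 26.5 61.8 644.9
378.1 3.1 2.1 321.9 33.6 3.2
61.1 231 6.4 7.2 61.7 0.2 4.1
292.3 3.8 0.2 7.5 11.8 3.2 16.9 13.8
5.1 617 94.6 190.3 174 99.3 228.9 24.3 7.9
413.4 73.7 12.9 22.6 420.2 184.6 6.4 141.6 7.1 9.5
19.3 883.6 26 55.6 1.5 0.5 0.2 0.2 2 0.2 51.4
2.3 0.2 13.9 3.7 49.1 3.4 82.4 37.5 48.8 59.7 0.2 264.8
167.8 8.1 656.3 199 36.1 76.7 243.8 349.4 8.9 421.8 0.2 23 334
83.9 9.5 52.2 96.4 39.4 6.1 52.3 9 43.1 14.9 7.3 1 163.2 0.2
0.2 20.6 38.4 34.5 3.5 10 16.3 7.4 3.4 3.5 10.1 52.2 5.8 1.3 257.1
5.2 12.3 4.3 23.7 1.6 6.6 23.9 7.1 13.1 15.6 23.1 19.4 4.5 266.5 0.3 425.2
8.4 449.7 90.3 2.6 7.2 222.3 9.7 13.1 1710.6 6.7 636.3 234.2 11.4 15.2 50 27.2 5.7
126.1 83 16.3 24.3 144.9 75.5 6.6 45 11.1 215.6 5.4 95.3 305.1 48.7 41.4 279.6 10.5 32.2
19.3 58.2 590.5 59.6 79.7 56.9 1.3 4.2 17.9 666.3 10.3 29.7 49.5 3.6 29 396.4 79.8 13.7 15.6

0.0688799311201 0.021036978963 0.03038996961 0.020695979304 0.00996599003401 0.018622981377 0.024988975011 0.0719679280321 0.026813973186 0.0850719149281 0.156716843283 0.019275980724 0.050651949348 0.0817119182881 0.044802955197 0.0805349194651 0.0563859436141 0.027997972002 0.037403962596 0.0660829339171

# A R N D C Q E G H I L K M F P S T W Y V
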