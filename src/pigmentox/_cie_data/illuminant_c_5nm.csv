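# CIE standard illuminant C, relative spectral power distribution on a
# 5 nm grid, 380-780 nm (CIE 15 tabulation). Absolute scale is irrelevant
# downstream: tristimulus integration renormalises to Y_n = 100.
wavelength_nm,power
380,33.00
385,39.92
390,47.40
395,55.17
400,63.30
405,71.81
410,80.60
415,89.53
420,98.10
425,105.80
430,112.40
435,117.75
440,121.50
445,123.45
450,124.00
455,123.60
460,123.10
465,123.30
470,123.80
475,124.09
480,123.90
485,122.92
490,120.70
495,116.90
500,112.10
505,106.98
510,102.30
515,98.81
520,96.90
525,96.78
530,98.00
535,99.94
540,102.10
545,103.95
550,105.20
555,105.67
560,105.30
565,104.11
570,102.30
575,100.15
580,97.80
585,95.43
590,93.20
595,91.22
600,89.70
605,88.83
610,88.40
615,88.19
620,88.10
625,88.06
630,88.00
635,87.86
640,87.80
645,87.99
650,88.20
655,88.20
660,87.90
665,87.22
670,86.30
675,85.30
680,84.00
685,82.21
690,80.20
695,78.24
700,76.30
705,74.36
710,72.40
715,70.40
720,68.30
725,66.30
730,64.40
735,62.80
740,61.50
745,60.20
750,59.20
755,58.50
760,58.10
765,58.00
770,58.20
775,58.50
780,59.10
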