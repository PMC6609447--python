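# name: blue_light_hazard
# description: retinal blue-light photochemical hazard B(lambda); synthetic stand-in following the widely published piecewise tabulation, native 5-nm grid 300-700 nm, unit peak 435-440 nm
# columns: wavelength_nm,weight
300.0,0.01
305.0,0.01
310.0,0.01
315.0,0.01
320.0,0.01
325.0,0.01
330.0,0.01
335.0,0.01
340.0,0.01
345.0,0.01
350.0,0.01
355.0,0.01
360.0,0.01
365.0,0.01
370.0,0.01
375.0,0.01
380.0,0.01
385.0,0.013
390.0,0.025
395.0,0.05
400.0,0.1
405.0,0.2
410.0,0.4
415.0,0.8
420.0,0.9
425.0,0.95
430.0,0.98
435.0,1.0
440.0,1.0
445.0,0.97
450.0,0.94
455.0,0.9
460.0,0.8
465.0,0.7
470.0,0.62
475.0,0.55
480.0,0.45
485.0,0.32
490.0,0.22
495.0,0.16
500.0,0.1
505.0,0.07943282347242814
510.0,0.06309573444801933
515.0,0.05011872336272722
520.0,0.039810717055349734
525.0,0.03162277660168379
530.0,0.025118864315095794
535.0,0.0199526231496888
540.0,0.015848931924611134
545.0,0.012589254117941675
550.0,0.01
555.0,0.007943282347242814
560.0,0.00630957344480193
565.0,0.005011872336272725
570.0,0.003981071705534973
575.0,0.0031622776601683794
580.0,0.0025118864315095794
585.0,0.001995262314968879
590.0,0.001584893192461114
595.0,0.0012589254117941675
600.0,0.001
605.0,0.001
610.0,0.001
615.0,0.001
620.0,0.001
625.0,0.001
630.0,0.001
635.0,0.001
640.0,0.001
645.0,0.001
650.0,0.001
655.0,0.001
660.0,0.001
665.0,0.001
670.0,0.001
675.0,0.001
680.0,0.001
685.0,0.001
690.0,0.001
695.0,0.001
700.0,0.001
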