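# name: photopic_V
# description: photopic luminous efficiency V(lambda); synthetic stand-in transcribed from the widely published 5-nm tabulation, linearly interpolated to 1 nm (peak 1.0 at 555 nm)
# columns: wavelength_nm,weight
380.0,3.9e-05
381.0,4.4e-05
382.0,4.9e-05
383.0,5.4e-05
384.0,5.9e-05
385.0,6.4e-05
386.0,7.52e-05
387.0,8.64e-05
388.0,9.76e-05
389.0,0.0001088
390.0,0.00012
391.0,0.0001394
392.0,0.0001588
393.0,0.0001782
394.0,0.00019759999999999998
395.0,0.000217
396.0,0.00025279999999999996
397.0,0.00028859999999999997
398.0,0.00032439999999999997
399.0,0.0003602
400.0,0.000396
401.0,0.00044479999999999997
402.0,0.0004936
403.0,0.0005424
404.0,0.0005912000000000001
405.0,0.00064
406.0,0.000754
407.0,0.0008680000000000001
408.0,0.000982
409.0,0.001096
410.0,0.00121
411.0,0.0014039999999999999
412.0,0.001598
413.0,0.001792
414.0,0.001986
415.0,0.00218
416.0,0.0025440000000000003
417.0,0.002908
418.0,0.003272
419.0,0.0036360000000000003
420.0,0.004
421.0,0.00466
422.0,0.00532
423.0,0.00598
424.0,0.00664
425.0,0.0073
426.0,0.00816
427.0,0.00902
428.0,0.00988
429.0,0.01074
430.0,0.0116
431.0,0.012648
432.0,0.013696
433.0,0.014744
434.0,0.015792
435.0,0.01684
436.0,0.018072
437.0,0.019304
438.0,0.020536
439.0,0.021768
440.0,0.023
441.0,0.02436
442.0,0.02572
443.0,0.02708
444.0,0.02844
445.0,0.0298
446.0,0.03144
447.0,0.03308
448.0,0.03472
449.0,0.036359999999999996
450.0,0.038
451.0,0.04
452.0,0.042
453.0,0.044
454.0,0.046
455.0,0.048
456.0,0.0504
457.0,0.0528
458.0,0.0552
459.0,0.0576
460.0,0.06
461.0,0.06278
462.0,0.06556
463.0,0.06834
464.0,0.07111999999999999
465.0,0.0739
466.0,0.077316
467.0,0.080732
468.0,0.084148
469.0,0.087564
470.0,0.09098
471.0,0.095304
472.0,0.09962800000000001
473.0,0.103952
474.0,0.10827600000000001
475.0,0.1126
476.0,0.117884
477.0,0.123168
478.0,0.128452
479.0,0.133736
480.0,0.13902
481.0,0.145076
482.0,0.15113200000000002
483.0,0.157188
484.0,0.163244
485.0,0.1693
486.0,0.177044
487.0,0.184788
488.0,0.192532
489.0,0.200276
490.0,0.20802
491.0,0.218136
492.0,0.228252
493.0,0.238368
494.0,0.24848399999999998
495.0,0.2586
496.0,0.27148
497.0,0.28436
498.0,0.29724
499.0,0.31012
500.0,0.323
501.0,0.33986
502.0,0.35672
503.0,0.37358
504.0,0.39044
505.0,0.4073
506.0,0.42644
507.0,0.44558
508.0,0.46472
509.0,0.48386
510.0,0.503
511.0,0.52404
512.0,0.54508
513.0,0.56612
514.0,0.58716
515.0,0.6082
516.0,0.62856
517.0,0.6489199999999999
518.0,0.66928
519.0,0.6896399999999999
520.0,0.71
521.0,0.72664
522.0,0.7432799999999999
523.0,0.75992
524.0,0.77656
525.0,0.7932
526.0,0.80696
527.0,0.82072
528.0,0.83448
529.0,0.84824
530.0,0.862
531.0,0.87257
532.0,0.88314
533.0,0.89371
534.0,0.9042800000000001
535.0,0.91485
536.0,0.9226800000000001
537.0,0.9305100000000001
538.0,0.93834
539.0,0.94617
540.0,0.954
541.0,0.95926
542.0,0.9645199999999999
543.0,0.96978
544.0,0.9750399999999999
545.0,0.9803
546.0,0.9832299999999999
547.0,0.9861599999999999
548.0,0.98909
549.0,0.99202
550.0,0.99495
551.0,0.99596
552.0,0.99697
553.0,0.99798
554.0,0.99899
555.0,1.0
556.0,0.999
557.0,0.998
558.0,0.997
559.0,0.996
560.0,0.995
561.0,0.99172
562.0,0.98844
563.0,0.98516
564.0,0.98188
565.0,0.9786
566.0,0.97328
567.0,0.96796
568.0,0.9626399999999999
569.0,0.95732
570.0,0.952
571.0,0.94468
572.0,0.93736
573.0,0.93004
574.0,0.92272
575.0,0.9154
576.0,0.90632
577.0,0.89724
578.0,0.88816
579.0,0.87908
580.0,0.87
581.0,0.85926
582.0,0.84852
583.0,0.83778
584.0,0.82704
585.0,0.8163
586.0,0.80444
587.0,0.7925800000000001
588.0,0.78072
589.0,0.76886
590.0,0.757
591.0,0.74458
592.0,0.73216
593.0,0.7197399999999999
594.0,0.70732
595.0,0.6949
596.0,0.68212
597.0,0.6693399999999999
598.0,0.65656
599.0,0.64378
600.0,0.631
601.0,0.61816
602.0,0.60532
603.0,0.59248
604.0,0.5796399999999999
605.0,0.5668
606.0,0.55404
607.0,0.54128
608.0,0.52852
609.0,0.51576
610.0,0.503
611.0,0.49064
612.0,0.47828
613.0,0.46592
614.0,0.45355999999999996
615.0,0.4412
616.0,0.42916
617.0,0.41712
618.0,0.40508
619.0,0.39304
620.0,0.381
621.0,0.369
622.0,0.357
623.0,0.345
624.0,0.333
625.0,0.321
626.0,0.3098
627.0,0.29860000000000003
628.0,0.2874
629.0,0.2762
630.0,0.265
631.0,0.2554
632.0,0.24580000000000002
633.0,0.23620000000000002
634.0,0.2266
635.0,0.217
636.0,0.2086
637.0,0.2002
638.0,0.1918
639.0,0.1834
640.0,0.175
641.0,0.16763999999999998
642.0,0.16027999999999998
643.0,0.15292
644.0,0.14556
645.0,0.1382
646.0,0.13196
647.0,0.12572
648.0,0.11948
649.0,0.11324
650.0,0.107
651.0,0.10192
652.0,0.09684
653.0,0.09176000000000001
654.0,0.08668000000000001
655.0,0.0816
656.0,0.07748000000000001
657.0,0.07336000000000001
658.0,0.06924
659.0,0.06512
660.0,0.061
661.0,0.057715999999999996
662.0,0.054432
663.0,0.051148
664.0,0.047864000000000004
665.0,0.04458
666.0,0.042064000000000004
667.0,0.039548
668.0,0.037032
669.0,0.034516000000000005
670.0,0.032
671.0,0.03024
672.0,0.02848
673.0,0.02672
674.0,0.02496
675.0,0.0232
676.0,0.02196
677.0,0.02072
678.0,0.01948
679.0,0.01824
680.0,0.017
681.0,0.015984
682.0,0.014968
683.0,0.013952
684.0,0.012936
685.0,0.01192
686.0,0.011178
687.0,0.010436
688.0,0.009694000000000001
689.0,0.008952
690.0,0.00821
691.0,0.0077126
692.0,0.0072152
693.0,0.0067178
694.0,0.0062204
695.0,0.005723
696.0,0.0053988
697.0,0.005074599999999999
698.0,0.0047504
699.0,0.0044262
700.0,0.004102
701.0,0.0038674
702.0,0.0036328
703.0,0.0033982
704.0,0.0031636
705.0,0.002929
706.0,0.0027614000000000002
707.0,0.0025938000000000003
708.0,0.0024262
709.0,0.0022586
710.0,0.002091
711.0,0.0019696
712.0,0.0018482
713.0,0.0017268000000000001
714.0,0.0016054
715.0,0.001484
716.0,0.0013966
717.0,0.0013092
718.0,0.0012217999999999999
719.0,0.0011344
720.0,0.001047
721.0,0.0009855999999999999
722.0,0.0009242
723.0,0.0008627999999999999
724.0,0.0008014
725.0,0.00074
726.0,0.000696
727.0,0.000652
728.0,0.000608
729.0,0.0005639999999999999
730.0,0.00052
731.0,0.00048819999999999994
732.0,0.0004564
733.0,0.00042459999999999997
734.0,0.0003928
735.0,0.000361
736.0,0.0003386
737.0,0.0003162
738.0,0.0002938
739.0,0.0002714
740.0,0.000249
741.0,0.00023359999999999999
742.0,0.0002182
743.0,0.0002028
744.0,0.0001874
745.0,0.000172
746.0,0.0001616
747.0,0.00015120000000000002
748.0,0.0001408
749.0,0.0001304
750.0,0.00012
751.0,0.00011296
752.0,0.00010592
753.0,9.888e-05
754.0,9.184e-05
755.0,8.48e-05
756.0,7.984e-05
757.0,7.488e-05
758.0,6.992000000000001e-05
759.0,6.496e-05
760.0,6e-05
761.0,5.648e-05
762.0,5.296e-05
763.0,4.944e-05
764.0,4.592e-05
765.0,4.24e-05
766.0,3.992e-05
767.0,3.744e-05
768.0,3.4960000000000004e-05
769.0,3.248e-05
770.0,3e-05
771.0,2.824e-05
772.0,2.648e-05
773.0,2.472e-05
774.0,2.296e-05
775.0,2.12e-05
776.0,1.994e-05
777.0,1.868e-05
778.0,1.742e-05
779.0,1.616e-05
780.0,1.49e-05
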