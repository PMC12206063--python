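wavelength_nm,extinction_M_cm
440.0,0.15442250441853397
441.0,0.18645967466452132
442.0,0.22479974223534563
443.0,0.27060979315945727
444.0,0.3252582287381479
445.0,0.3903466355576973
446.0,0.4677461779720425
447.0,0.5596390643145938
448.0,0.6685656904637388
449.0,0.797478119383757
450.0,0.949800612633511
451.0,1.1294979892389065
452.0,1.34115264832869
453.0,1.5900511540027156
454.0,1.8822813433936256
455.0,2.2248409810353142
456.0,2.6257590435781544
457.0,3.0942307775745044
458.0,3.6407677283463675
459.0,4.277363988549613
460.0,5.017679959539277
461.0,5.877244955454203
462.0,6.873680007384479
463.0,8.026942241249365
464.0,9.35959220617394
465.0,10.897085518200212
466.0,12.668090155020334
467.0,14.704830688951972
468.0,17.043460675453026
469.0,19.72446432098172
470.0,22.79308843489791
471.0,26.299805523435566
472.0,30.300808707771296
473.0,34.85853894129959
474.0,40.04224476210438
475.0,45.9285745443095
476.0,52.60220090591515
477.0,60.15647659073598
478.0,68.69412076852059
479.0,78.32793429117433
480.0,89.18154200575954
481.0,101.39015975882033
482.0,115.10138323444812
483.0,130.47599525398493
484.0,147.68878763270817
485.0,166.92939314332585
486.0,188.40312258344093
487.0,212.33180139081477
488.0,238.9545997033941
489.0,268.5288492283604
490.0,301.3308397740784
491.0,337.6565878192966
492.0,377.822569054041
493.0,422.1664064351707
494.0,471.04750496528055
495.0,524.8476241350194
496.0,583.9713787738688
497.0,648.8466589403963
498.0,719.9249594562834
499.0,797.6816097543716
500.0,882.6158948735812
501.0,975.2510586953146
502.0,1076.1341808776538
503.0,1185.835919404342
504.0,1304.9501112222529
505.0,1434.0932240887153
506.0,1573.9036534818783
507.0,1725.0408592339854
508.0,1888.1843374180607
509.0,2064.0324239403226
510.0,2253.300927248921
511.0,2456.7215885487553
512.0,2675.040368894971
513.0,2909.015563506834
514.0,3159.415744581128
515.0,3427.0175347723143
516.0,3712.6032143287193
517.0,4016.9581656142514
518.0,4340.868159390152
519.0,4685.11648776956
520.0,5050.480949181289
521.0,5437.7306909833815
522.0,5847.622915550935
523.0,6280.899455730534
524.0,6738.28322551328
525.0,7220.474551643915
526.0,7728.147391672774
527.0,8261.945443694161
528.0,8822.478152727004
529.0,9410.316618414117
530.0,10025.989408481571
531.0,10669.978282248858
532.0,11342.713828456059
533.0,12044.571021819074
534.0,12775.864703081546
535.0,13536.844987944623
536.0,14327.692611162875
537.0,15148.514213332366
538.0,15999.337579494597
539.0,16880.10684066222
540.0,17790.67765175272
541.0,18730.812362200715
542.0,19700.175198701276
543.0,20698.327483098976
544.0,21724.72291234811
545.0,22778.702931685424
546.0,23859.492236619044
547.0,24966.194443975208
548.0,26097.787976972093
549.0,27253.122214011022
550.0,28430.913955480446
551.0,29629.74426723964
552.0,30848.05576346013
553.0,32084.150395023276
554.0,33336.18781256649
555.0,34602.184375404926
556.0,35880.01287879899
557.0,37167.403072265246
558.0,38461.94304072528
559.0,39761.08151815197
560.0,41062.131199919364
561.0,42362.27311522713
562.0,43658.562114708504
563.0,44947.93352062549
564.0,46227.21097791539
565.0,47493.11553381738
566.0,48742.275961944986
567.0,49971.240333580165
568.0,51176.488824774424
569.0,52354.44773271497
570.0,53501.50465893235
571.0,54614.02480050647
572.0,55688.36827370499
573.0,56720.908377716434
574.0,57708.05068959166
575.0,58646.25286546102
576.0,59532.04500783648
577.0,60362.05044462614
578.0,61133.00675265995
579.0,61841.78684732108
580.0,62485.41995054795
581.0,63061.11224224576
582.0,63566.26699522458
583.0,63998.50399133093
584.0,64355.6780165933
585.0,64635.89623604695
586.0,64837.534254489015
587.0,64959.25067773918
588.0,65000.0
589.0,64959.04365653032
590.0,64835.9590969262
591.0,64630.64675266127
592.0,64343.33479294904
593.0,63974.58158518515
594.0,63525.27579991374
595.0,62996.63412510751
596.0,62390.19658020718
597.0,61707.81944646456
598.0,60951.66585629391
599.0,60124.19411017932
600.0,59228.14381482902
601.0,58266.51996034499
602.0,57242.57507683257
603.0,56159.78963178322
604.0,55021.85084842202
605.0,53832.63014175466
606.0,52596.15938304855
607.0,51316.6062147544
608.0,49998.24864627869
609.0,48645.449166460836
610.0,47262.62861104894
611.0,45854.24002290751
612.0,44424.74273918351
613.0,42978.57693330023
614.0,41520.138830583885
615.0,40053.75680473679
616.0,38583.668548470436
617.0,37113.99949565069
618.0,35648.74265455995
619.0,34191.73999264334
620.0,32746.665492687884
621.0,31317.009979104412
622.0,29906.067791165813
623.0,28516.925358021017
624.0,27152.451708366843
625.0,25815.290926117978
626.0,24507.8565425524
627.0,23232.32783548724
628.0,21990.647987292603
629.0,20784.52403618856
630.0,19615.42853946865
631.0,18484.60285319846
632.0,17393.061920662676
633.0,16341.600451456978
634.0,15330.800364688786
635.0,14361.039363277865
636.0,13432.500501816921
637.0,12545.182607819068
638.0,11698.911415372133
639.0,10893.351271144022
640.0,10128.017275223858
641.0,9402.287723306927
642.0,8715.416722090878
643.0,8066.546856288764
644.0,7454.721793215409
645.0,6878.898719298514
646.0,6337.960511934086
647.0,5830.727559678376
648.0,5355.969153681531
649.0,4912.41438336374
650.0,4498.762479464841
651.0,4113.692557624814
652.0,3755.8727254498044
653.0,3423.968525474427
654.0,3116.6506954467795
655.0,2832.6022358549917
656.0,2570.524782513689
657.0,2329.144289280866
658.0,2107.2160325404834
659.0,1903.5289549365662
660.0,1716.909370967397
661.0,1546.2240614414484
662.0,1390.3827874693561
663.0,1248.3402576373994
664.0,1119.0975843047831
665.0,1001.7032666244849
666.0,895.2537389460155
667.0,798.8935237636159
668.0,711.8150283741257
669.0,633.2580239565017
670.0,562.5088449322253
671.0,498.8993452658493
672.0,441.8056468701415
673.0,390.6467135417604
674.0,344.88278192046243
675.0,304.01367888394054
676.0,267.5770526051724
677.0,235.14654224970937
678.0,206.32990901322086
679.0,180.76714892751255
680.0,158.12860562494572
681.0,138.1130990716659
682.0,120.4460841803783
683.0,104.87785121097166
684.0,91.18177797599569
685.0,79.15264209839323
686.0,68.60499992846087
687.0,59.371637220486775
688.0,51.30209529905724
689.0,44.26127521058861
690.0,38.12812125524937
691.0,32.794384324451876
692.0,28.163464624488565
693.0,24.149332641553194
694.0,20.67552659031245
695.0,17.674224079759792
696.0,15.0853853182152
697.0,12.855964855734493
698.0,10.939188618464033
699.0,9.293892817303998
700.0,7.88392120447499
701.0,6.677577098370551
702.0,5.6471265919225235
703.0,4.768349395548103
704.0,4.02013383599508
705.0,3.384112630971496
706.0,2.8443361807806364
707.0,2.3869802572493612
708.0,2.0000851225384344
709.0,1.6733232719676028
710.0,1.3977931622864714
711.0,1.1658364568536614
712.0,0.9708764893770007
713.0,0.807275816051344
714.0,0.6702108903245204
715.0,0.5555620536850753
716.0,0.4598171886685353
717.0,0.3799875258684099
718.0,0.31353423450402185
719.0,0.2583045556415049
720.0,0.2124763582706847
721.0,0.17451011104743885
722.0,0.1431073666855084
723.0,0.11717495189594286
724.0,0.09579414368330565
725.0,0.07819419303785788
726.0,0.06372962998368183
727.0,0.05186084996039145
728.0,0.04213754105911093
729.0,0.03418456514200278
730.0,0.027689953791827114
731.0,0.022394722802509526
732.0,0.01808424696188072
733.0,0.014580970607248596
734.0,0.01173825924850529
735.0,0.009435223826444154
736.0,0.00757237225766655
737.0,0.006067963140097715
738.0,0.004854954158891139
739.0,0.003878453121591443
740.0,0.0030935929205277673
741.0,0.0024637633034045236
742.0,0.0019591423420005803
743.0,0.0015554791151488362
744.0,0.0012330865376750074
745.0,0.0009760096255340719
746.0,0.0007713399260382516
747.0,0.0006086514824446496
748.0,0.0004795376518022013
749.0,0.00037723144858392457
750.0,0.0002962949274208687
751.0,0.00023236551897230654
752.0,0.00018194925706439184
753.0,0.0001422525378578018
754.0,0.00011104548075193448
755.0,8.655115727873719e-05
756.0,6.735595393508791e-05
757.0,5.233716827743883e-05
758.0,4.0604630795810706e-05
759.0,3.145372041519434e-05
760.0,2.4327617944370122e-05
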