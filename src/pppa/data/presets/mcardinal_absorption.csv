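wavelength_nm,extinction_M_cm
440.0,0.0034529969041656636
441.0,0.004299115074026638
442.0,0.005344353771137474
443.0,0.006633529711829952
444.0,0.008221056228451512
445.0,0.010172884929029158
446.0,0.01256881511197438
447.0,0.015505235271461906
448.0,0.01909837120943357
449.0,0.02348812685465779
450.0,0.028842617033614504
451.0,0.03536350630834981
452.0,0.04329228476894325
453.0,0.05291763052798245
454.0,0.06458402980434408
455.0,0.07870184910267738
456.0,0.09575908029625138
457.0,0.11633500860855749
458.0,0.1411160857655199
459.0,0.1709143261517839
460.0,0.2066885828371147
461.0,0.24956910301251314
462.0,0.300885808838078
463.0,0.3622008000749659
464.0,0.43534562923413644
465.0,0.5224639583618409
466.0,0.6260602689779645
467.0,0.749055363005687
468.0,0.8948494626206965
469.0,1.0673937905597979
470.0,1.2712715892171609
471.0,1.511789616365921
472.0,1.7950812369937852
473.0,2.1282223138190193
474.0,2.5193611826960836
475.0,2.9778640823088054
476.0,3.5144774890969144
477.0,4.141508886907413
478.0,4.8730275748636
479.0,5.725087184674098
480.0,6.7159716381525705
481.0,7.866466324992548
482.0,9.200156317576148
483.0,10.743753461364536
484.0,12.527454183648198
485.0,14.585329847437208
486.0,16.955751438257987
487.0,19.6818503067511
488.0,22.81201659637559
489.0,26.40043686039092
490.0,30.507672212863355
491.0,35.20127816213684
492.0,40.55646703963235
493.0,46.6568136598933
494.0,53.59500452773971
495.0,61.47363054392195
496.0,70.40602275099413
497.0,80.517130206062
498.0,91.94443856709678
499.0,104.8389274358795
500.0,119.36606391540123
501.0,135.70682921565182
502.0,154.05877448303056
503.0,174.63710133994906
504.0,197.675761908394
505.0,223.4285723610669
506.0,252.1703333039902
507.0,284.1979495538598
508.0,319.83154114146595
509.0,359.4155366594978
510.0,403.31973938992036
511.0,451.94035600428924
512.0,505.7009770415626
513.0,565.0534978439977
514.0,630.4789681842985
515.0,702.4883584576413
516.0,781.6232300511782
517.0,868.4562973509919
518.0,963.5918688107178
519.0,1067.6661545943127
520.0,1181.347428523101
521.0,1305.3360324075747
522.0,1440.3642113285518
523.0,1587.1957690488885
524.0,1746.6255334820924
525.0,1919.4786230110496
526.0,2106.609505429591
527.0,2308.9008423593345
528.0,2527.2621131595583
529.0,2762.628013581663
530.0,3015.956625702402
531.0,3288.2273569806416
532.0,3580.438647597884
533.0,3893.6054465399166
534.0,4228.756458131664
535.0,4586.931161926021
536.0,4969.176609947671
537.0,5376.544006283691
538.0,5810.0850748760495
539.0,6270.848222091565
540.0,6759.87450121188
541.0,7278.193386393141
542.0,7826.8183638912515
543.0,8406.74234843933
544.0,9018.932932610083
545.0,9664.3274768157
546.0,10343.828047315867
547.0,11058.296209252185
548.0,11808.547681342297
549.0,12595.346858492741
550.0,13419.401208275334
551.0,14281.35554701001
552.0,15181.786201164263
553.0,16121.195059973223
554.0,17100.003525662993
555.0,18118.546368479725
556.0,19177.06549494108
557.0,20275.703639383322
558.0,21414.497991015847
559.0,22593.373771347895
560.0,23812.137780038258
561.0,25070.471930945572
562.0,26367.92680441555
563.0,27703.9152466094
564.0,29077.706051912086
565.0,30488.41777010203
566.0,31935.012685936257
567.0,33416.29102501297
568.0,34930.88544610111
569.0,36477.25588644552
570.0,38053.684832719984
571.0,39658.27309615152
572.0,41288.93617570817
573.0,42943.40129795423
574.0,44619.20522605053
575.0,46313.692933234284
576.0,48024.01723777711
577.0,49747.13949672425
578.0,51479.83145450922
579.0,53218.67833968033
580.0,54960.08329835361
581.0,56700.27324653478
582.0,58435.30621507139
583.0,60161.08025068335
584.0,61873.34392428676
585.0,63567.7084837248
586.0,65239.66167214175
587.0,66884.583215715
588.0,68497.7619654673
589.0,70074.41465763388
590.0,71609.70623580176
591.0,73098.77165606251
592.0,74536.73907403591
593.0,75918.7542901743
594.0,77240.0063076073
595.0,78495.75383530937
596.0,79681.35254895037
597.0,80792.28290280729
598.0,81824.17826894486
599.0,82772.8531648759
600.0,83634.33131842571
601.0,84404.87330885202
602.0,85081.0035166852
603.0,85659.5361114737
604.0,86137.59980682489
605.0,86512.66111593977
606.0,86782.54584831606
607.0,86945.45859943551
608.0,87000.0
609.0,86945.18150950981
610.0,86780.43756050122
611.0,86505.63488433124
612.0,86121.0788767164
613.0,85627.51689094013
614.0,85026.13837834608
615.0,84318.57182899004
616.0,83506.87849966192
617.0,82593.54295142178
618.0,81581.46045380877
619.0,80473.92134747078
620.0,79274.5924906173
621.0,77987.49594692329
622.0,76616.98510283744
623.0,75167.71843023293
624.0,73644.63113558025
625.0,72052.90495896393
626.0,70397.93640500343
627.0,68685.30370282513
628.0,66920.73280348071
629.0,65110.06273049374
630.0,63259.21060248089
631.0,61374.13664604543
632.0,59460.80951244562
633.0,57525.17220303262
634.0,55573.10889631997
635.0,53610.41295403231
636.0,51642.756364875815
637.0,49675.66086340939
638.0,47714.47093764178
639.0,45764.32891323032
640.0,43830.1522748284
641.0,41916.613356647445
642.0,40028.121505098854
643.0,38168.80778688967
644.0,36342.51228658332
645.0,34552.77400880406
646.0,32802.823372339364
647.0,31095.577256729073
648.0,29433.63653683779
649.0,27819.286017667764
650.0,26254.496660519577
651.0,24740.92997274255
652.0,23279.944416886967
653.0,21872.603681180877
654.0,20519.686641968066
655.0,19221.698840079604
656.0,17978.885287047262
657.0,16791.244413542445
658.0,15658.542971344239
659.0,14580.331701377383
660.0,13555.961583761164
661.0,12584.600491195424
662.0,11665.250074183175
663.0,10796.762715340345
664.0,9977.858400149855
665.0,9207.141362753395
666.0,8483.116377511777
667.0,7804.204579877211
668.0,7168.758713389127
669.0,6575.077713117621
670.0,6021.420549437556
671.0,5506.0192694362895
672.0,5027.091186371277
673.0,4582.850180250387
674.0,4171.517084674921
675.0,3791.329146452066
676.0,3440.5485550567837
677.0,3117.470048729774
678.0,2820.427612784955
679.0,2547.8002935304808
680.0,2298.0171580640545
681.0,2069.5614360831696
682.0,1860.9738847666767
683.0,1670.8554217608269
684.0,1497.8690743771713
685.0,1340.7412953281566
686.0,1198.2626967431283
687.0,1069.288254883609
688.0,952.737037977676
689.0,847.591508987933
690.0,752.8964539862092
691.0,667.7575852019829
692.0,591.3398658108048
693.0,522.8656012020485
694.0,461.6123388781574
695.0,406.91061635235116
696.0,358.1415934869231
697.0,314.73460270345714
698.0,276.16464744846485
699.0,241.9498762568245
700.0,211.64905675954273
701.0,184.85907106515285
702.0,161.21245113373712
703.0,140.37497008237744
704.0,122.04330282940961
705.0,105.94276711631093
706.0,91.82515375040147
707.0,79.46665289511307
708.0,68.66588140027662
709.0,59.242014512633986
710.0,51.03302383394916
711.0,43.894022095804814
712.0,37.69571418970008
713.0,32.32295292023274
714.0,27.673397128572052
715.0,23.65626915290926
716.0,20.191208041303423
717.0,17.207214499213862
718.0,14.641683227790322
719.0,12.439518078545351
720.0,10.55232530445114
721.0,8.937680116280584
722.0,7.558461746111686
723.0,6.382252267887462
724.0,5.380794518947261
725.0,4.529504598377233
726.0,3.807034580429467
727.0,3.194881267395299
728.0,2.6770370101668273
729.0,2.239678840941253
730.0,1.8708923864449694
731.0,1.5604272576349008
732.0,1.2994808396276778
733.0,1.0805076307148758
734.0,0.897051499357435
735.0,0.7435984410861776
736.0,0.6154476217563473
737.0,0.5085986884700255
738.0,0.4196535138746138
739.0,0.34573071293555274
740.0,0.2843914333776857
741.0,0.23357507170964892
742.0,0.1915437061790651
743.0,0.15683416638380046
744.0,0.12821677692996294
745.0,0.10465991991220977
746.0,0.08529965859354337
747.0,0.06941375302390855
748.0,0.05639947803296386
749.0,0.04575472565160371
750.0,0.037061938152137826
751.0,0.029974475135666596
752.0,0.02420506901051727
753.0,0.019516068351240427
754.0,0.015711208532614773
755.0,0.012628684198471407
756.0,0.010135329021799843
757.0,0.008121735279823095
758.0,0.006498169412669679
759.0,0.005191160331976239
760.0,0.0041406551397833195
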