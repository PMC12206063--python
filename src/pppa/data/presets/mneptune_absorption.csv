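wavelength_nm,extinction_M_cm
440.0,0.0026592045124034422
441.0,0.0033108127581584455
442.0,0.004115766697312767
443.0,0.005108580352788584
444.0,0.006331158244899441
445.0,0.00783429069247073
446.0,0.009679432327612453
447.0,0.01194081336997641
448.0,0.014707941046345393
449.0,0.018088557462782436
450.0,0.022212130359220365
451.0,0.027233964628269394
452.0,0.03334003539677239
453.0,0.04075265799281407
454.0,0.04973712640104659
455.0,0.060609469998613615
456.0,0.07374549861895222
457.0,0.0895913284686592
458.0,0.10867560627919348
459.0,0.13162367646171863
460.0,0.1591739660929504
461.0,0.19219689542342966
462.0,0.23171665738104857
463.0,0.2789362483335944
464.0,0.33526617423778327
465.0,0.40235730126716485
466.0,0.4821383680634899
467.0,0.5768587278319658
468.0,0.6891369424780077
469.0,0.822015907672488
470.0,0.9790252468683882
471.0,1.1642517735231805
472.0,1.3824188836618805
473.0,1.6389758048951069
474.0,1.9401976924211217
475.0,2.2932976266056317
476.0,2.7065516295344056
477.0,3.1894378784229507
478.0,3.752791350757025
479.0,4.408975188197293
480.0,5.172070112140485
481.0,6.05808326177587
482.0,7.08517785376554
483.0,8.273925079441653
484.0,9.6475796586716
485.0,11.232380457221758
486.0,13.057877544405576
487.0,15.157287017842801
488.0,17.56787485008235
489.0,20.331370915473467
490.0,23.49441423289477
491.0,27.109030308772045
492.0,31.233141283395028
493.0,35.93110937026266
494.0,41.274313831707595
495.0,47.34176145336518
496.0,54.220730164558695
497.0,62.00744510122016
498.0,70.8077860229366
499.0,80.73802457705662
500.0,91.9255894520906
501.0,104.50985698216866
502.0,118.64296425704653
503.0,134.49064126179985
504.0,152.23305802140686
505.0,172.06568216312047
506.0,194.2001417398545
507.0,218.86508758745524
508.0,246.307048925037
509.0,276.7912753584638
510.0,310.60255792097314
511.0,348.04602129065955
512.0,389.44787887108845
513.0,435.1561420177913
514.0,485.54127434882764
515.0,540.9967818007123
516.0,601.9397288899878
517.0,668.8111715231777
518.0,742.076496670323
519.0,822.2256592852754
520.0,909.7733070235375
521.0,1005.2587835782473
522.0,1109.2460018277354
523.0,1222.323178462937
524.0,1345.1024223367838
525.0,1478.219169445291
526.0,1622.3314582043977
527.0,1778.1190395181081
528.0,1946.282317030924
529.0,2127.5411139077173
530.0,2322.633263471965
531.0,2532.3130220425633
532.0,2757.349303322508
533.0,2998.5237346916597
534.0,3256.6285367220858
535.0,3532.464228149924
536.0,3826.8371593849874
537.0,4140.556878402382
538.0,4474.433333525233
539.0,4829.273918162469
540.0,5205.880363002252
541.0,5605.045481475177
542.0,6027.5497744909635
543.0,6474.157900522242
544.0,6945.615017067535
545.0,7442.642999386804
546.0,7965.936542185782
547.0,8516.159149653982
548.0,9093.939018964757
549.0,9699.864822057629
550.0,10334.481390281006
551.0,10998.285306318052
552.0,11691.720407793167
553.0,12415.173207105816
554.0,13168.968232407133
555.0,13953.363295265995
556.0,14768.544691506348
557.0,15614.622342973364
558.0,16491.62488963289
559.0,17399.49474345183
560.0,18338.083117960497
561.0,19307.14505026843
562.0,20306.33443558439
563.0,21335.19909796356
564.0,22393.175925035743
565.0,23479.58609881421
566.0,24593.630459284246
567.0,25734.385042251368
568.0,26900.796837802
569.0,28091.679820595975
570.0,29305.711307956768
571.0,30541.42870623163
572.0,31797.22671002813
573.0,33071.35502256245
574.0,34361.91666833776
575.0,35666.86697157123
576.0,36984.01327506972
577.0,38311.01547448879
578.0,39645.38744197837
579.0,40984.49941101819
580.0,42325.581390686115
581.0,43665.727672618734
582.0,45001.90248746877
583.0,46330.94685972166
584.0,47649.58670031279
585.0,48954.442165627144
586.0,50242.0382992356
587.0,51508.81695922879
588.0,52751.15001938287
589.0,53965.35381679851
590.0,55147.70480228411
591.0,56294.45633282975
592.0,57401.85652828053
593.0,58466.16709703079
594.0,59483.683018502175
595.0,60450.75295362905
596.0,61363.80023884684
597.0,62219.34430446079
598.0,63014.022345049496
599.0,63744.611058007875
600.0,64408.048256718655
601.0,65001.45415739179
602.0,65522.15213353918
603.0,65967.68872952572
604.0,66335.85272479618
605.0,66624.69304330993
606.0,66832.53530847329
607.0,66957.99685243885
608.0,67000.0
609.0,66957.78346134664
610.0,66830.91168452393
611.0,66619.28203735854
612.0,66323.12970965517
613.0,65943.0302493447
614.0,65479.899670680315
615.0,64934.99209818774
616.0,64309.89493652125
617.0,63606.52158327885
618.0,62827.10172879526
619.0,61974.16931356945
620.0,61050.54823990068
621.0,60059.33595912483
622.0,59003.88507919665
623.0,57887.783158915016
624.0,56714.83087452732
625.0,55489.018761500956
626.0,54214.50274868081
627.0,52895.57871366992
628.0,51536.656296933426
629.0,50142.23221773656
630.0,48716.86333754275
631.0,47265.13971592004
632.0,45791.65790038916
633.0,44300.99468509409
634.0,42797.68156383262
635.0,41286.18009103638
636.0,39770.85834996183
637.0,38255.968710901485
638.0,36745.627043931025
639.0,35243.793530878516
640.0,33754.2552001552
641.0,32280.610286153777
642.0,30826.254492432454
643.0,29394.369215190894
644.0,27987.911760931976
645.0,26609.60756999853
646.0,25261.944436169397
647.0,23947.16869196377
648.0,22667.283309978528
649.0,21424.04785268667
650.0,20218.980186836918
651.0,19053.359864066104
652.0,17928.233056683064
653.0,16844.418926886425
654.0,15802.517298986902
655.0,14802.917497532568
656.0,13845.808209565133
657.0,12931.188226521193
658.0,12058.877920460505
659.0,11228.531310256145
660.0,10439.648575999978
661.0,9691.588884024062
662.0,8983.583390462905
663.0,8314.748298020726
664.0,7684.097848391268
665.0,7090.557141430776
666.0,6532.974681532058
667.0,6010.134561514634
668.0,5520.7682045640395
669.0,5063.565595159547
670.0,4637.185940371451
671.0,4240.267713244039
672.0,3871.438040079029
673.0,3529.3214031813327
674.0,3212.547639922065
675.0,2919.759227727453
676.0,2649.617852744879
677.0,2400.810267412585
678.0,2172.0534489263446
679.0,1962.099076626922
680.0,1769.7373516125479
681.0,1593.8001864088776
682.0,1433.1637963145672
683.0,1286.7507271031657
684.0,1153.5313561295457
685.0,1032.524905597546
686.0,922.8000078366621
687.0,823.4748629563426
688.0,733.7170292471758
689.0,652.7428862320863
690.0,579.8168093916784
691.0,514.2500943509524
692.0,455.39966677383813
693.0,402.66661241996843
694.0,355.4945598257074
695.0,313.3679459265233
696.0,275.8101926853316
697.0,242.38182047277735
698.0,212.67852159824304
699.0,186.3292150483591
700.0,162.99410118263637
701.0,142.36273288925565
702.0,124.15211753977455
703.0,108.10486201746309
704.0,93.98737114448787
705.0,81.58810800911301
706.0,70.71592300318275
707.0,61.19845682727099
708.0,52.880621308259
709.0,45.623160601683644
710.0,39.30129421694935
711.0,33.803442303665776
712.0,29.030032766780522
713.0,24.89238903052406
714.0,21.31169663924514
715.0,18.218046359137016
716.0,15.54955102031413
717.0,13.251533005141708
718.0,11.275779037493697
719.0,9.57985875014412
720.0,8.126503395381912
721.0,6.883041009089645
722.0,5.820884333212447
723.0,4.915067838488045
724.0,4.143830261718006
725.0,3.4882391734629263
726.0,2.931854217112348
727.0,2.4604258036262645
728.0,2.0616262032319246
729.0,1.7248101418742983
730.0,1.4408021826645168
731.0,1.2017083478337742
732.0,1.0007496121270623
733.0,0.8321150719298469
734.0,0.6908327638729672
735.0,0.5726562707215391
736.0,0.4739654098583364
737.0,0.39167944974128405
738.0,0.32318144171953017
739.0,0.266252388122782
740.0,0.21901409237132116
741.0,0.1798796529258216
742.0,0.14751067027583176
743.0,0.12078033503120264
744.0,0.09874165579663813
745.0,0.0806001682082535
746.0,0.06569054167548742
747.0,0.053456568420711184
748.0,0.04343408078400665
749.0,0.03523639791560286
750.0,0.028541952370037177
751.0,0.023083791196432894
752.0,0.018640685329938587
753.0,0.015029615856702398
754.0,0.012099436456151606
755.0,0.00972553840571936
756.0,0.007805368327133213
757.0,0.006254669698254567
758.0,0.005004337363780097
759.0,0.003997790140717334
760.0,0.0031887803950055448
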