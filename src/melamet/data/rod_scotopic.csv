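wavelength_nm,rod
380,0.000590772317
381,0.00067080948
382,0.000762588232
383,0.000867933925
384,0.000988969026
385,0.00112816334
386,0.00128839296
387,0.00147300959
388,0.00168592203
389,0.00193169199
390,0.00221564694
391,0.00254693387
392,0.00293614998
393,0.00339212124
394,0.00392451665
395,0.00454372225
396,0.0052606242
397,0.00608627814
398,0.00703144265
399,0.00810595749
400,0.00931795386
401,0.010698543
402,0.0122900751
403,0.0141159167
404,0.0161989595
405,0.0185604057
406,0.0212182204
407,0.0241852412
408,0.0274669664
409,0.0310590815
410,0.0349448345
411,0.0391713685
412,0.043818023
413,0.0489025963
414,0.0544381027
415,0.0604314195
416,0.0668818358
417,0.0737795451
418,0.0811041326
419,0.0888231234
420,0.096890672
421,0.10535853
422,0.11431167
423,0.12373854
424,0.133620586
425,0.143931597
426,0.154637106
427,0.165693893
428,0.177049588
429,0.188642434
430,0.200401204
431,0.212389056
432,0.224699057
433,0.237293651
434,0.250129659
435,0.263158206
436,0.276324724
437,0.28956904
438,0.302825545
439,0.316023472
440,0.329087262
441,0.342076885
442,0.355085831
443,0.368085218
444,0.3810459
445,0.393938617
446,0.406734138
447,0.419403419
448,0.431917738
449,0.444248848
450,0.456369107
451,0.468255089
452,0.479913714
453,0.49136726
454,0.502643052
455,0.513773355
456,0.524795269
457,0.535750638
458,0.546685995
459,0.557652532
460,0.568706118
461,0.579760308
462,0.59070499
463,0.601566216
464,0.612372854
465,0.623156559
466,0.633951764
467,0.644795679
468,0.655728314
469,0.666792528
470,0.678034102
471,0.689472383
472,0.70107414
473,0.712806879
474,0.724635827
475,0.736523882
476,0.748431574
477,0.760317049
478,0.772136074
479,0.783842068
480,0.795386158
481,0.80693211
482,0.818625396
483,0.830384541
484,0.842123336
485,0.853750816
486,0.865171337
487,0.876284751
488,0.886986692
489,0.897168982
490,0.90672016
491,0.916110712
492,0.925751124
493,0.935431343
494,0.944932434
495,0.954026743
496,0.9624786
497,0.970045579
498,0.976480357
499,0.981533166
500,0.984954865
501,0.987420435
502,0.989750037
503,0.991914746
504,0.993885464
505,0.995632979
506,0.997128018
507,0.998341319
508,0.999243708
509,0.99980618
510,1
511,0.99899911
512,0.996161531
513,0.991740475
514,0.985993287
515,0.979177822
516,0.971549453
517,0.963358712
518,0.954849586
519,0.946258422
520,0.93781344
521,0.928860994
522,0.918710399
523,0.907527471
524,0.895475644
525,0.882714447
526,0.869398243
527,0.855675225
528,0.841686655
529,0.82756634
530,0.813440321
531,0.798985645
532,0.783876494
533,0.768225854
534,0.752142342
535,0.735729595
536,0.719085798
537,0.702303323
538,0.68546848
539,0.668661377
540,0.651955868
541,0.635179619
542,0.618171122
543,0.601012123
544,0.583779273
545,0.566543928
546,0.54937203
547,0.53232406
548,0.515455055
549,0.498814678
550,0.482447342
551,0.466258218
552,0.450161127
553,0.434206234
554,0.418439199
555,0.402901216
556,0.387629098
557,0.372655391
558,0.358008514
559,0.343712938
560,0.329789368
561,0.316181317
562,0.302840139
563,0.289792774
564,0.277062503
565,0.264669103
566,0.252629017
567,0.24095554
568,0.229659017
569,0.218747043
570,0.208224674
571,0.198055313
572,0.188207145
573,0.178688751
574,0.169506367
575,0.16066405
576,0.152163853
577,0.144005993
578,0.136189028
579,0.128710018
580,0.121564694
581,0.114723457
582,0.108162841
583,0.101885227
584,0.0958909906
585,0.0901787131
586,0.08474539
587,0.0795866338
588,0.0746968651
589,0.0700694943
590,0.0656970913
591,0.061557428
592,0.057631195
593,0.0539141026
594,0.0504010396
595,0.0470862093
596,0.0439632556
597,0.0410253795
598,0.0382654455
599,0.0356760784
600,0.0332497492
601,0.0309726928
602,0.0288326997
603,0.0268243508
604,0.0249420708
605,0.0231801896
606,0.0215329961
607,0.0199947856
608,0.0185599015
609,0.0172227706
610,0.0159779338
611,0.0148174267
612,0.013734224
613,0.0127243868
614,0.0117840133
615,0.0109092637
616,0.0100963812
617,0.0093417093
618,0.00864170622
619,0.00799295588
620,0.00739217653
621,0.00683511954
622,0.00631798189
623,0.00583832063
624,0.00539378504
625,0.0049821211
626,0.00460117449
627,0.00424889236
628,0.00392332408
629,0.00362262094
630,0.00334503511
631,0.00308845436
632,0.00285101211
633,0.00263144702
634,0.00242855655
635,0.00224119767
636,0.00206828692
637,0.00190879995
638,0.0017617707
639,0.00162629009
640,0.00150150451
641,0.00138640326
642,0.0012800893
643,0.00118194644
644,0.00109139316
645,0.00100788186
646,0.000930897936
647,0.000859958725
648,0.00079461236
649,0.000734436515
650,0.000679037111
651,0.000627988847
652,0.000580894714
653,0.00053744325
654,0.0004973477
655,0.000460344065
656,0.000426189293
657,0.000394659621
658,0.000365549039
659,0.000338667881
660,0.000313841525
661,0.000290906666
662,0.000269711692
663,0.000250119187
664,0.00023200304
665,0.00021524748
666,0.000199746192
667,0.000185401513
668,0.000172123699
669,0.000159830257
670,0.000148445336
671,0.000137898467
672,0.000128125817
673,0.00011906959
674,0.000110676328
675,0.000102896588
676,9.56846398e-05
677,8.89981891e-05
678,8.27981205e-05
679,7.70482583e-05
680,7.17151454e-05
681,6.67675982e-05
682,6.21762597e-05
683,5.79140787e-05
684,5.39561788e-05
685,5.02796729e-05
686,4.68634958e-05
687,4.36882503e-05
688,4.07360679e-05
689,3.79904815e-05
690,3.54363089e-05
691,3.30598954e-05
692,3.08487355e-05
693,2.87909693e-05
694,2.68756124e-05
695,2.50924895e-05
696,2.3432173e-05
697,2.1885927e-05
698,2.04456551e-05
699,1.91038523e-05
700,1.78535607e-05
701,1.66882863e-05
702,1.56020063e-05
703,1.45891762e-05
704,1.3644653e-05
705,1.27636658e-05
706,1.19417879e-05
707,1.11749113e-05
708,1.04592227e-05
709,9.79118211e-06
710,9.16750251e-06
711,8.5850972e-06
712,8.04111581e-06
713,7.53294839e-06
714,7.05816645e-06
715,6.61451007e-06
716,6.19987602e-06
717,5.81230663e-06
718,5.44997958e-06
719,5.1111983e-06
720,4.79438315e-06
721,4.49806049e-06
722,4.22084521e-06
723,3.96144614e-06
724,3.71866364e-06
725,3.49138278e-06
726,3.27856709e-06
727,3.07925278e-06
728,2.89254339e-06
729,2.71760486e-06
730,2.55366098e-06
731,2.39998603e-06
732,2.2559145e-06
733,2.12083282e-06
734,1.99416703e-06
735,1.87538031e-06
736,1.7639705e-06
737,1.65946789e-06
738,1.56143309e-06
739,1.46945511e-06
740,1.38314945e-06
741,1.30215925e-06
742,1.22614169e-06
743,1.15477053e-06
744,1.08774252e-06
745,1.02477568e-06
746,9.65607678e-07
747,9.0999439e-07
748,8.57708536e-07
749,8.08538435e-07
750,7.62286861e-07
751,7.18778978e-07
752,6.77853164e-07
753,6.39350268e-07
754,6.03121311e-07
755,5.69026813e-07
756,5.36936166e-07
757,5.06727052e-07
758,4.78284892e-07
759,4.51502346e-07
760,4.26278837e-07
761,4.0251378e-07
762,3.80116755e-07
763,3.59010422e-07
764,3.39121552e-07
765,3.20380831e-07
766,3.02722681e-07
767,2.8608508e-07
768,2.70409393e-07
769,2.55640209e-07
770,2.41725176e-07
771,2.2860965e-07
772,2.1624149e-07
773,2.04576443e-07
774,1.93572958e-07
775,1.8319202e-07
776,1.73396989e-07
777,1.64153455e-07
778,1.55429092e-07
779,1.47193535e-07
780,1.39418255e-07
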