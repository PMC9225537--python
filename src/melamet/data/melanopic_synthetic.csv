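wavelength_nm,ipRGC
380,0.000586135232
381,0.000641842588
382,0.000705287656
383,0.000777465114
384,0.00085949201
385,0.000952623387
386,0.0010582699
387,0.00117801768
388,0.00131365066
389,0.00146717573
390,0.00164085104
391,0.00183517619
392,0.00205105264
393,0.00229212287
394,0.00256295079
395,0.00286926142
396,0.00321825086
397,0.0036189919
398,0.00408297008
399,0.00462479917
400,0.00526318468
401,0.00604147649
402,0.0070069162
403,0.00819014555
404,0.00962344778
405,0.0113380759
406,0.01336024
407,0.0157055538
408,0.0183719479
409,0.0213314231
410,0.0245215297
411,0.0279939323
412,0.0318812881
413,0.0362098571
414,0.0410015721
415,0.0462722914
416,0.0520298541
417,0.0582719887
418,0.0649841459
419,0.0721373549
420,0.0796862259
421,0.0876959415
422,0.0962707852
423,0.105404094
424,0.115079414
425,0.125269213
426,0.135933662
427,0.147019566
428,0.158459494
429,0.170171183
430,0.182057289
431,0.194117916
432,0.206419655
433,0.218958027
434,0.231735001
435,0.2447597
436,0.258049067
437,0.271628532
438,0.285532666
439,0.29980588
440,0.314503171
441,0.329597621
442,0.345006308
443,0.360707127
444,0.376675943
445,0.392886606
446,0.409310979
447,0.425918971
448,0.442678583
449,0.459555972
450,0.476515511
451,0.493521397
452,0.510555649
453,0.527609862
454,0.544678066
455,0.561756814
456,0.578845252
457,0.595945174
458,0.613061069
459,0.630200163
460,0.647372441
461,0.664534797
462,0.68161714
463,0.698590481
464,0.715425091
465,0.732090537
466,0.748555739
467,0.764789024
468,0.780758191
469,0.79643058
470,0.811773149
471,0.826770638
472,0.841402727
473,0.855627943
474,0.869404122
475,0.882688559
476,0.895438191
477,0.907609781
478,0.91916013
479,0.930046297
480,0.940225836
481,0.949689708
482,0.958434288
483,0.966426647
484,0.973635186
485,0.980029859
486,0.985582382
487,0.990266454
488,0.994057963
489,0.996935194
490,0.998879021
491,0.999897318
492,1
493,0.99917519
494,0.997413972
495,0.994710506
496,0.991062129
497,0.986469429
498,0.980936294
499,0.974469934
500,0.967080879
501,0.958786327
502,0.949615657
503,0.939602026
504,0.928780919
505,0.917189909
506,0.904868401
507,0.891857365
508,0.878199076
509,0.863936833
510,0.8491147
511,0.833770827
512,0.817935236
513,0.801640982
514,0.784922025
515,0.767813052
516,0.750349319
517,0.732566486
518,0.714500465
519,0.696187275
520,0.67766291
521,0.658979472
522,0.640186558
523,0.621316042
524,0.60239939
525,0.583467594
526,0.564551111
527,0.54567981
528,0.526882929
529,0.508189027
530,0.489625954
531,0.471228895
532,0.4530332
533,0.43506543
534,0.417350822
535,0.399913285
536,0.382775386
537,0.365958334
538,0.349481963
539,0.333364717
540,0.317623628
541,0.302279491
542,0.287348514
543,0.272839193
544,0.258759203
545,0.245115332
546,0.231913407
547,0.219158239
548,0.206853553
549,0.195001943
550,0.183604826
551,0.172668354
552,0.162196579
553,0.15218591
554,0.142631514
555,0.133527347
556,0.12486621
557,0.116639806
558,0.108838812
559,0.101452961
560,0.0944711285
561,0.0878823918
562,0.0816753982
563,0.0758372599
564,0.0703544878
565,0.0652131228
566,0.0603988614
567,0.0558971758
568,0.0516934264
569,0.0477729663
570,0.0441212369
571,0.0407235216
572,0.0375653585
573,0.0346329543
574,0.0319129087
575,0.0293922564
576,0.0270585011
577,0.024899642
578,0.0229041931
579,0.021061196
580,0.0193602274
581,0.0177915571
582,0.0163458536
583,0.0150141263
584,0.0137879469
585,0.012659427
586,0.0116211957
587,0.0106663759
588,0.00978856027
589,0.00898178718
590,0.00824051671
591,0.00755976862
592,0.00693490275
593,0.00636145439
594,0.0058352923
595,0.00535259757
596,0.00490984323
597,0.00450377468
598,0.00413139101
599,0.00378992719
600,0.00347683728
601,0.00318977096
602,0.00292658959
603,0.00268533955
604,0.00246421885
605,0.00226156678
606,0.00207585393
607,0.00190567284
608,0.00174972916
609,0.00160683318
610,0.00147589208
611,0.00135591148
612,0.00124595741
613,0.00114515959
614,0.00105272628
615,0.000967937011
616,0.000890135895
617,0.000818725671
618,0.000753162253
619,0.000692949825
620,0.00063763639
621,0.000586826798
622,0.000540163689
623,0.000497304785
624,0.000457936025
625,0.000421769277
626,0.000388540236
627,0.000358006476
628,0.000329945665
629,0.00030415391
630,0.000280444245
631,0.000258642774
632,0.000238589785
633,0.000220141203
634,0.000203165093
635,0.000187540619
636,0.000173157092
637,0.000159913109
638,0.000147715753
639,0.000136479872
640,0.000126127419
641,0.00011658788
642,0.000107795949
643,9.96905566e-05
644,9.22158401e-05
645,8.53206826e-05
646,7.89582916e-05
647,7.30858181e-05
648,6.76640103e-05
649,6.26568983e-05
650,5.80315083e-05
651,5.37583764e-05
652,4.98105595e-05
653,4.61625905e-05
654,4.27910433e-05
655,3.96743657e-05
656,3.67927267e-05
657,3.41278765e-05
658,3.16630176e-05
659,2.93826868e-05
660,2.72726473e-05
661,2.53197332e-05
662,2.35118015e-05
663,2.18377181e-05
664,2.02872308e-05
665,1.88508984e-05
666,1.75200239e-05
667,1.62865945e-05
668,1.5143226e-05
669,1.40831123e-05
670,1.30999781e-05
671,1.21880547e-05
672,1.13420165e-05
673,1.0556932e-05
674,9.82825127e-06
675,9.15177564e-06
676,8.52362962e-06
677,7.94023527e-06
678,7.39828863e-06
679,6.89473803e-06
680,6.42676424e-06
681,5.99177909e-06
682,5.58738516e-06
683,5.21134801e-06
684,4.86160253e-06
685,4.53623961e-06
686,4.23349397e-06
687,3.95173289e-06
688,3.68944597e-06
689,3.44523554e-06
690,3.21780804e-06
691,3.00597792e-06
692,2.80864687e-06
693,2.62478568e-06
694,2.45344074e-06
695,2.2937283e-06
696,2.14482917e-06
697,2.00598387e-06
698,1.87648815e-06
699,1.75568878e-06
700,1.6429798e-06
701,1.53779896e-06
702,1.43962445e-06
703,1.34797192e-06
704,1.26239167e-06
705,1.18246614e-06
706,1.10780746e-06
707,1.03805536e-06
708,9.72875061e-07
709,9.11955453e-07
710,8.55007357e-07
711,8.01761923e-07
712,7.51969156e-07
713,7.05396548e-07
714,6.61827814e-07
715,6.21061721e-07
716,5.82911004e-07
717,5.47201366e-07
718,5.13770546e-07
719,4.82467464e-07
720,4.53151418e-07
721,4.25691354e-07
722,3.99965174e-07
723,3.7585911e-07
724,3.53267131e-07
725,3.32090401e-07
726,3.12236773e-07
727,2.93620323e-07
728,2.7616091e-07
729,2.59783779e-07
730,2.44419182e-07
731,2.30002036e-07
732,2.16471592e-07
733,2.03771146e-07
734,1.91847752e-07
735,1.8065197e-07
736,1.70137621e-07
737,1.6026157e-07
738,1.50983511e-07
739,1.42265782e-07
740,1.3407318e-07
741,1.26372799e-07
742,1.19133871e-07
743,1.12327626e-07
744,1.05927153e-07
745,9.99072812e-08
746,9.42444583e-08
747,8.89166458e-08
748,8.39032171e-08
749,7.91848643e-08
750,7.47435102e-08
751,7.05622277e-08
752,6.66251636e-08
753,6.29174684e-08
754,5.94252298e-08
755,5.61354122e-08
756,5.30357988e-08
757,5.01149387e-08
758,4.73620971e-08
759,4.47672086e-08
760,4.23208344e-08
761,4.00141214e-08
762,3.78387649e-08
763,3.57869732e-08
764,3.38514347e-08
765,3.20252875e-08
766,3.03020905e-08
767,2.86757966e-08
768,2.71407278e-08
769,2.56915521e-08
770,2.43232612e-08
771,2.30311502e-08
772,2.1810799e-08
773,2.06580538e-08
774,1.95690108e-08
775,1.85400006e-08
776,1.75675736e-08
777,1.6648486e-08
778,1.57796877e-08
779,1.49583096e-08
780,1.41816532e-08
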