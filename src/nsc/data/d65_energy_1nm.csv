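wavelength,d65
300,0.0341
301,0.36014
302,0.68618
303,1.01222
304,1.33826
305,1.6643
306,1.99034
307,2.31638
308,2.64242
309,2.96846
310,3.2945
311,4.98864
312,6.68278
313,8.37692
314,10.07106
315,11.7652
316,13.45936
317,15.15352
318,16.84768
319,18.54184
320,20.236
321,21.91774
322,23.59948
323,25.28122
324,26.96296
325,28.6447
326,30.32646
327,32.00822
328,33.68998
329,35.37174
330,37.0535
331,37.34302
332,37.63254
333,37.92206
334,38.21158
335,38.5011
336,38.79064
337,39.08018
338,39.36972
339,39.65926
340,39.9488
341,40.44508
342,40.94136
343,41.43764
344,41.93392
345,42.4302
346,42.9265
347,43.4228
348,43.9191
349,44.4154
350,44.9117
351,45.08436
352,45.25702
353,45.42968
354,45.60234
355,45.775
356,45.94766
357,46.12032
358,46.29298
359,46.46564
360,46.6383
361,47.18338
362,47.72846
363,48.27354
364,48.81862
365,49.3637
366,49.90878
367,50.45386
368,50.99894
369,51.54402
370,52.0891
371,51.87774
372,51.66638
373,51.45502
374,51.24366
375,51.0323
376,50.82094
377,50.60958
378,50.39822
379,50.18686
380,49.9755
381,50.44276
382,50.91002
383,51.37728
384,51.84454
385,52.3118
386,52.77908
387,53.24636
388,53.71364
389,54.18092
390,54.6482
391,57.45886
392,60.26952
393,63.08018
394,65.89084
395,68.7015
396,71.51218
397,74.32286
398,77.13354
399,79.94422
400,82.7549
401,83.628
402,84.5011
403,85.3742
404,86.2473
405,87.1204
406,87.99352
407,88.86664
408,89.73976
409,90.61288
410,91.486
411,91.68058
412,91.87516
413,92.06974
414,92.26432
415,92.4589
416,92.65348
417,92.84806
418,93.04264
419,93.23722
420,93.4318
421,92.75684
422,92.08188
423,91.40692
424,90.73196
425,90.057
426,89.38206
427,88.70712
428,88.03218
429,87.35724
430,86.6823
431,88.50056
432,90.31882
433,92.13708
434,93.95534
435,95.7736
436,97.59188
437,99.41016
438,101.22844
439,103.04672
440,104.865
441,106.0792
442,107.2934
443,108.5076
444,109.7218
445,110.936
446,112.1504
447,113.3648
448,114.5792
449,115.7936
450,117.008
451,117.0884
452,117.1688
453,117.2492
454,117.3296
455,117.41
456,117.4904
457,117.5708
458,117.6512
459,117.7316
460,117.812
461,117.5168
462,117.2216
463,116.9264
464,116.6312
465,116.336
466,116.041
467,115.746
468,115.451
469,115.156
470,114.861
471,114.9672
472,115.0734
473,115.1796
474,115.2858
475,115.392
476,115.4982
477,115.6044
478,115.7106
479,115.8168
480,115.923
481,115.2118
482,114.5006
483,113.7894
484,113.0782
485,112.367
486,111.6558
487,110.9446
488,110.2334
489,109.5222
490,108.811
491,108.8652
492,108.9194
493,108.9736
494,109.0278
495,109.082
496,109.1364
497,109.1908
498,109.2452
499,109.2996
500,109.354
501,109.1988
502,109.0436
503,108.8884
504,108.7332
505,108.578
506,108.4228
507,108.2676
508,108.1124
509,107.9572
510,107.802
511,107.5008
512,107.1996
513,106.8984
514,106.5972
515,106.296
516,105.9948
517,105.6936
518,105.3924
519,105.0912
520,104.79
521,105.0798
522,105.3696
523,105.6594
524,105.9492
525,106.239
526,106.529
527,106.819
528,107.109
529,107.399
530,107.689
531,107.3606
532,107.0322
533,106.7038
534,106.3754
535,106.047
536,105.7186
537,105.3902
538,105.0618
539,104.7334
540,104.405
541,104.369
542,104.333
543,104.297
544,104.261
545,104.225
546,104.1892
547,104.1534
548,104.1176
549,104.0818
550,104.046
551,103.6414
552,103.2368
553,102.8322
554,102.4276
555,102.023
556,101.6184
557,101.2138
558,100.8092
559,100.4046
560,100.0
561,99.63342
562,99.26684
563,98.90026
564,98.53368
565,98.1671
566,97.80052
567,97.43394
568,97.06736
569,96.70078
570,96.3342
571,96.27958
572,96.22496
573,96.17034
574,96.11572
575,96.0611
576,96.00648
577,95.95186
578,95.89724
579,95.84262
580,95.788
581,95.07776
582,94.36752
583,93.65728
584,92.94704
585,92.2368
586,91.52656
587,90.81632
588,90.10608
589,89.39584
590,88.6856
591,88.81766
592,88.94972
593,89.08178
594,89.21384
595,89.3459
596,89.47796
597,89.61002
598,89.74208
599,89.87414
600,90.0062
601,89.96548
602,89.92476
603,89.88404
604,89.84332
605,89.8026
606,89.7619
607,89.7212
608,89.6805
609,89.6398
610,89.5991
611,89.40906
612,89.21902
613,89.02898
614,88.83894
615,88.6489
616,88.45886
617,88.26882
618,88.07878
619,87.88874
620,87.6987
621,87.25768
622,86.81666
623,86.37564
624,85.93462
625,85.4936
626,85.0526
627,84.6116
628,84.1706
629,83.7296
630,83.2886
631,83.32966
632,83.37072
633,83.41178
634,83.45284
635,83.4939
636,83.53496
637,83.57602
638,83.61708
639,83.65814
640,83.6992
641,83.33196
642,82.96472
643,82.59748
644,82.23024
645,81.863
646,81.49576
647,81.12852
648,80.76128
649,80.39404
650,80.0268
651,80.04558
652,80.06436
653,80.08314
654,80.10192
655,80.1207
656,80.13948
657,80.15826
658,80.17704
659,80.19582
660,80.2146
661,80.42092
662,80.62724
663,80.83356
664,81.03988
665,81.2462
666,81.45252
667,81.65884
668,81.86516
669,82.07148
670,82.2778
671,81.87844
672,81.47908
673,81.07972
674,80.68036
675,80.281
676,79.88164
677,79.48228
678,79.08292
679,78.68356
680,78.2842
681,77.4279
682,76.5716
683,75.7153
684,74.859
685,74.0027
686,73.14642
687,72.29014
688,71.43386
689,70.57758
690,69.7213
691,69.91008
692,70.09886
693,70.28764
694,70.47642
695,70.6652
696,70.85398
697,71.04276
698,71.23154
699,71.42032
700,71.6091
701,71.88308
702,72.15706
703,72.43104
704,72.70502
705,72.979
706,73.253
707,73.527
708,73.801
709,74.075
710,74.349
711,73.0745
712,71.8
713,70.5255
714,69.251
715,67.9765
716,66.702
717,65.4275
718,64.153
719,62.8785
720,61.604
721,62.43216
722,63.26032
723,64.08848
724,64.91664
725,65.7448
726,66.57296
727,67.40112
728,68.22928
729,69.05744
730,69.8856
731,70.40574
732,70.92588
733,71.44602
734,71.96616
735,72.4863
736,73.00644
737,73.52658
738,74.04672
739,74.56686
740,75.087
741,73.93756
742,72.78812
743,71.63868
744,70.48924
745,69.3398
746,68.19038
747,67.04096
748,65.89154
749,64.74212
750,63.5927
751,61.87524
752,60.15778
753,58.44032
754,56.72286
755,55.0054
756,53.28796
757,51.57052
758,49.85308
759,48.13564
760,46.4182
761,48.45692
762,50.49564
763,52.53436
764,54.57308
765,56.6118
766,58.65052
767,60.68924
768,62.72796
769,64.76668
770,66.8054
771,66.46314
772,66.12088
773,65.77862
774,65.43636
775,65.0941
776,64.75184
777,64.40958
778,64.06732
779,63.72506
780,63.3828
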