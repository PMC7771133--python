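wavelength,d65
300,0.002
301,0.0022422728
302,0.0024845456
303,0.0027268184
304,0.0029690912
305,0.003211364
306,0.0046488894
307,0.0060864148
308,0.0075239402
309,0.0089614656
310,0.010398991
311,0.0118938028
312,0.0133886146
313,0.0148834264
314,0.0163782382
315,0.01787305
316,0.0209054884
317,0.0239379268
318,0.0269703652
319,0.0300028036
320,0.033035242
321,0.0372757336
322,0.0415162252
323,0.0457567168
324,0.0499972084
325,0.0542377
326,0.058134561
327,0.062031422
328,0.065928283
329,0.069825144
330,0.073722005
331,0.0746757276
332,0.0756294502
333,0.0765831728
334,0.0775368954
335,0.078490618
336,0.0835319048
337,0.0885731916
338,0.0936144784
339,0.0986557652
340,0.103697052
341,0.106217281
342,0.10873751
343,0.111257739
344,0.113777968
345,0.116298197
346,0.1201082474
347,0.1239182978
348,0.1277283482
349,0.1315383986
350,0.135348449
351,0.1387216822
352,0.1420949154
353,0.1454681486
354,0.1488413818
355,0.152214615
356,0.1539855412
357,0.1557564674
358,0.1575273936
359,0.1592983198
360,0.161069246
361,0.169715158
362,0.17836107
363,0.187006982
364,0.195652894
365,0.204298806
366,0.2072960088
367,0.2102932116
368,0.2132904144
369,0.2162876172
370,0.21928482
371,0.2208851978
372,0.2224855756
373,0.2240859534
374,0.2256863312
375,0.227286709
376,0.2321486204
377,0.2370105318
378,0.2418724432
379,0.2467343546
380,0.251596266
381,0.2508196504
382,0.2500430348
383,0.2492664192
384,0.2484898036
385,0.247713188
386,0.2547033828
387,0.2616935776
388,0.2686837724
389,0.2756739672
390,0.282664162
391,0.2891194352
392,0.2955747084
393,0.3020299816
394,0.3084852548
395,0.314940528
396,0.3396610002
397,0.3643814724
398,0.3891019446
399,0.4138224168
400,0.438542889
401,0.4551077238
402,0.4716725586
403,0.4882373934
404,0.5048022282
405,0.521367063
406,0.5257319396
407,0.5300968162
408,0.5344616928
409,0.5388265694
410,0.543191446
411,0.5500056436
412,0.5568198412
413,0.5636340388
414,0.5704482364
415,0.577262434
416,0.5813073418
417,0.5853522496
418,0.5893971574
419,0.5934420652
420,0.597486973
421,0.5954477178
422,0.5934084626
423,0.5913692074
424,0.5893299522
425,0.587290697
426,0.5816378022
427,0.5759849074
428,0.5703320126
429,0.5646791178
430,0.559026223
431,0.5698268744
432,0.5806275258
433,0.5914281772
434,0.6022288286
435,0.61302948
436,0.6263551222
437,0.6396807644
438,0.6530064066
439,0.6663320488
440,0.679657691
441,0.6936620912
442,0.7076664914
443,0.7216708916
444,0.7356752918
445,0.749679692
446,0.7592640356
447,0.7688483792
448,0.7784327228
449,0.7880170664
450,0.79760141
451,0.8048335898
452,0.8120657696
453,0.8192979494
454,0.8265301292
455,0.833762309
456,0.8356386694
457,0.8375150298
458,0.8393913902
459,0.8412677506
460,0.843144111
461,0.8440143944
462,0.8448846778
463,0.8457549612
464,0.8466252446
465,0.847495528
466,0.8450982724
467,0.8427010168
468,0.8403037612
469,0.8379065056
470,0.83550925
471,0.8412411408
472,0.8469730316
473,0.8527049224
474,0.8584368132
475,0.864168704
476,0.8690246716
477,0.8738806392
478,0.8787366068
479,0.8835925744
480,0.888448542
481,0.8826036406
482,0.8767587392
483,0.8709138378
484,0.8650689364
485,0.859224035
486,0.8565418064
487,0.8538595778
488,0.8511773492
489,0.8484951206
490,0.845812892
491,0.8523292698
492,0.8588456476
493,0.8653620254
494,0.8718784032
495,0.878394781
496,0.8772290906
497,0.8760634002
498,0.8748977098
499,0.8737320194
500,0.872566329
501,0.8722091634
502,0.8718519978
503,0.8714948322
504,0.8711376666
505,0.870780501
506,0.877589826
507,0.884399151
508,0.891208476
509,0.898017801
510,0.904827126
511,0.8992977572
512,0.8937683884
513,0.8882390196
514,0.8827096508
515,0.877180282
516,0.875619294
517,0.874058306
518,0.872497318
519,0.87093633
520,0.869375342
521,0.8776201414
522,0.8858649408
523,0.8941097402
524,0.9023545396
525,0.910599339
526,0.9130737536
527,0.9155481682
528,0.9180225828
529,0.9204969974
530,0.922971412
531,0.9201634416
532,0.9173554712
533,0.9145475008
534,0.9117395304
535,0.90893156
536,0.91343382
537,0.91793608
538,0.92243834
539,0.9269406
540,0.93144286
541,0.9328634922
542,0.9342841244
543,0.9357047566
544,0.9371253888
545,0.938546021
546,0.942334401
547,0.946122781
548,0.949911161
549,0.953699541
550,0.957487921
551,0.9587539158
552,0.9600199106
553,0.9612859054
554,0.9625519002
555,0.963817895
556,0.962326057
557,0.960834219
558,0.959342381
559,0.957850543
560,0.956358705
561,0.9600540754
562,0.9637494458
563,0.9674448162
564,0.9711401866
565,0.974835557
566,0.9726357748
567,0.9704359926
568,0.9682362104
569,0.9660364282
570,0.963836646
571,0.9635985882
572,0.9633605304
573,0.9631224726
574,0.9628844148
575,0.962646357
576,0.965907031
577,0.969167705
578,0.972428379
579,0.975689053
580,0.978949727
581,0.9794981652
582,0.9800466034
583,0.9805950416
584,0.9811434798
585,0.981691918
586,0.9729868776
587,0.9642818372
588,0.9555767968
589,0.9468717564
590,0.938166716
591,0.9389065354
592,0.9396463548
593,0.9403861742
594,0.9411259936
595,0.941865813
596,0.947857885
597,0.953849957
598,0.959842029
599,0.965834101
600,0.971826173
601,0.9751938794
602,0.9785615858
603,0.9819292922
604,0.9852969986
605,0.988664705
606,0.990931764
607,0.993198823
608,0.995465882
609,0.997732941
610,1.0
611,0.9990402076
612,0.9980804152
613,0.9971206228
614,0.9961608304
615,0.995201038
616,0.996141038
617,0.997081038
618,0.998021038
619,0.998961038
620,0.999901038
621,0.9974629384
622,0.9950248388
623,0.9925867392
624,0.9901486396
625,0.98771054
626,0.9860500254
627,0.9843895108
628,0.9827289962
629,0.9810684816
630,0.979407967
631,0.9798044558
632,0.9802009446
633,0.9805974334
634,0.9809939222
635,0.981390411
636,0.9812138506
637,0.9810372902
638,0.9808607298
639,0.9806841694
640,0.980507609
641,0.9793312132
642,0.9781548174
643,0.9769784216
644,0.9758020258
645,0.97462563
646,0.9715474604
647,0.9684692908
648,0.9653911212
649,0.9623129516
650,0.959234782
651,0.951261859
652,0.943288936
653,0.935316013
654,0.92734309
655,0.919370167
656,0.9198305362
657,0.9202909054
658,0.9207512746
659,0.9212116438
660,0.921672013
661,0.929200995
662,0.936729977
663,0.944258959
664,0.951787941
665,0.959316923
666,0.9584354718
667,0.9575540206
668,0.9566725694
669,0.9557911182
670,0.954909667
671,0.9537524132
672,0.9525951594
673,0.9514379056
674,0.9502806518
675,0.949123398
676,0.949485115
677,0.949846832
678,0.950208549
679,0.950570266
680,0.950931983
681,0.9379145722
682,0.9248971614
683,0.9118797506
684,0.8988623398
685,0.885844929
686,0.8705688236
687,0.8552927182
688,0.8400166128
689,0.8247405074
690,0.809464402
691,0.8151658058
692,0.8208672096
693,0.8265686134
694,0.8322700172
695,0.837971421
696,0.8345109144
697,0.8310504078
698,0.8275899012
699,0.8241293946
700,0.820668888
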