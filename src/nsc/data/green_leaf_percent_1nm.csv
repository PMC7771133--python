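wavelength,green_leaf
300,3.7993
301,3.8127
302,3.77016666667
303,3.7232
304,3.74085714286
305,3.784125
306,3.76957142857
307,3.758775
308,3.74083333333
309,3.7686
310,3.76542857143
311,3.81292857143
312,3.7734
313,3.79507142857
314,3.80219047619
315,3.80295
316,3.83869047619
317,3.8895
318,3.86030952381
319,3.90704761905
320,3.92721428571
321,3.98185714286
322,3.89364285714
323,3.86307142857
324,3.81785714286
325,3.72585714286
326,3.706
327,3.638825
328,3.61695
329,3.54065
330,3.5279
331,3.51214285714
332,3.58014285714
333,3.6845
334,3.713
335,3.73592857143
336,3.75642857143
337,3.794325
338,3.8073
339,3.86033333333
340,3.8655
341,3.82804761905
342,3.8505
343,3.84716666667
344,3.77102380952
345,3.7299
346,3.72821428571
347,3.7205
348,3.72814285714
349,3.72926190476
350,3.7061
351,3.726
352,3.7314
353,3.733325
354,3.75733333333
355,3.7612
356,3.75242857143
357,3.728
358,3.70492857143
359,3.6869047619
360,3.6708
361,3.671475
362,3.63228571429
363,3.616
364,3.6090952381
365,3.61615
366,3.6385
367,3.68161904762
368,3.70266666667
369,3.698
370,3.71497619048
371,3.73597619048
372,3.68128571429
373,3.6665
374,3.65404761905
375,3.60385
376,3.569
377,3.59033333333
378,3.62264285714
379,3.6449
380,3.7107
381,3.73
382,3.7420952381
383,3.77355
384,3.80595
385,3.84971428571
386,3.858
387,3.87345
388,3.89725
389,3.91383333333
390,3.95255
391,3.9980952381
392,4.0345
393,4.062
394,4.0918
395,4.141925
396,4.19875
397,4.2472
398,4.31333333333
399,4.373125
400,4.4404
401,4.500175
402,4.56721428571
403,4.6145
404,4.64630952381
405,4.68575
406,4.7328
407,4.7579
408,4.77525
409,4.815
410,4.846375
411,4.8757
412,4.91765
413,4.95275
414,4.970375
415,5.0069
416,5.05425
417,5.0913
418,5.12328571429
419,5.142375
420,5.1699
421,5.1939
422,5.21235714286
423,5.23375
424,5.244725
425,5.258
426,5.278
427,5.29095
428,5.29185
429,5.2954
430,5.30505
431,5.3083
432,5.309725
433,5.3091
434,5.3002
435,5.2965
436,5.311625
437,5.322875
438,5.32845
439,5.33835
440,5.3461
441,5.3532
442,5.36375
443,5.38165
444,5.387575
445,5.407325
446,5.4218
447,5.435425
448,5.45715
449,5.47605
450,5.50205
451,5.51815
452,5.5413
453,5.553825
454,5.575725
455,5.586375
456,5.595925
457,5.615
458,5.6203
459,5.6249
460,5.62915
461,5.6345
462,5.63225
463,5.633375
464,5.6367
465,5.6355
466,5.6491
467,5.654575
468,5.6527
469,5.65705
470,5.65015789474
471,5.663425
472,5.6475
473,5.6375
474,5.626225
475,5.62425
476,5.62781578947
477,5.62165
478,5.6239
479,5.613125
480,5.6268
481,5.65189473684
482,5.668875
483,5.6697
484,5.674775
485,5.676
486,5.68405
487,5.6891
488,5.6963
489,5.70335
490,5.710375
491,5.72513157895
492,5.73785
493,5.758225
494,5.7805
495,5.817
496,5.858725
497,5.9092
498,5.95155263158
499,5.9992
500,6.0486
501,6.11325
502,6.202225
503,6.28652631579
504,6.3643
505,6.46821052632
506,6.58885
507,6.702375
508,6.81085
509,6.93923684211
510,7.0746
511,7.2048
512,7.34963157895
513,7.50125
514,7.68285
515,7.9085
516,8.140375
517,8.37757894737
518,8.58334210526
519,8.8033
520,9.007275
521,9.222125
522,9.474525
523,9.75295
524,10.061225
525,10.382925
526,10.6961578947
527,10.9037894737
528,11.0665
529,11.2078421053
530,11.3595
531,11.511825
532,11.6411052632
533,11.7706
534,11.93875
535,12.0705
536,12.170675
537,12.2551
538,12.3458947368
539,12.44455
540,12.4997631579
541,12.5468684211
542,12.5915
543,12.6285263158
544,12.6596
545,12.6777105263
546,12.7079736842
547,12.7471
548,12.7951
549,12.8476315789
550,12.874
551,12.90365
552,12.9142
553,12.93075
554,12.94475
555,12.9385
556,12.9102894737
557,12.86
558,12.801275
559,12.7312368421
560,12.6736842105
561,12.5791578947
562,12.459
563,12.3165
564,12.1804210526
565,12.0539473684
566,11.91925
567,11.7609210526
568,11.5922631579
569,11.41965
570,11.2527894737
571,11.0773
572,10.8766578947
573,10.7116315789
574,10.5628157895
575,10.4292105263
576,10.30395
577,10.1681052632
578,10.0464473684
579,9.91444736842
580,9.81707894737
581,9.69178947368
582,9.60210526316
583,9.49965789474
584,9.39331578947
585,9.32026315789
586,9.22255263158
587,9.17176315789
588,9.09060526316
589,9.048
590,8.99560526316
591,8.97502631579
592,8.950225
593,8.90063157895
594,8.85539473684
595,8.82892105263
596,8.79978947368
597,8.77223684211
598,8.729
599,8.69697368421
600,8.66718421053
601,8.63481578947
602,8.60455263158
603,8.55505263158
604,8.534825
605,8.47834210526
606,8.44439473684
607,8.36584210526
608,8.30952631579
609,8.24394736842
610,8.16165789474
611,8.08165789474
612,7.99247368421
613,7.93952631579
614,7.882
615,7.81921052632
616,7.73684210526
617,7.68126315789
618,7.63373684211
619,7.59223684211
620,7.56489473684
621,7.53221052632
622,7.47827777778
623,7.45018421053
624,7.41978947368
625,7.38813157895
626,7.37302631579
627,7.36789473684
628,7.33478947368
629,7.30715789474
630,7.29552631579
631,7.29381578947
632,7.259
633,7.25826315789
634,7.22260526316
635,7.1595
636,7.13110526316
637,7.08452631579
638,7.04858333333
639,6.9955
640,6.95947368421
641,6.87331578947
642,6.81423684211
643,6.75639473684
644,6.73189473684
645,6.6725
646,6.5955
647,6.53757894737
648,6.4635
649,6.41818421053
650,6.377
651,6.2885
652,6.24484210526
653,6.22583333333
654,6.1825
655,6.13557894737
656,6.11392105263
657,6.06839473684
658,6.03258333333
659,5.99123684211
660,5.94792105263
661,5.89666666667
662,5.89268421053
663,5.85921052632
664,5.86315789474
665,5.84227777778
666,5.78663157895
667,5.81833333333
668,5.7975
669,5.78452631579
670,5.75455555556
671,5.76881578947
672,5.79776315789
673,5.85447368421
674,5.91933333333
675,5.95213157895
676,6.0465
677,6.08036111111
678,6.11639473684
679,6.15166666667
680,6.17155263158
681,6.24952631579
682,6.32563157895
683,6.39688888889
684,6.4885
685,6.62260526316
686,6.8325
687,6.95086111111
688,7.14360526316
689,7.33716666667
690,7.56173684211
691,7.81088888889
692,8.12731578947
693,8.48902631579
694,8.9295
695,9.46281578947
696,10.07975
697,10.6736666667
698,11.2165277778
699,11.76875
700,12.2940277778
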