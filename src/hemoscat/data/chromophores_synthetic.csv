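wavelength_nm,eps_oxy,eps_deoxy,mua_melanin
400,205478,130189,1427.86
401,223189,142442,1416.03
402,241577,155439,1404.34
403,260526,169171,1392.77
404,279902,183619,1381.32
405,299550,198758,1369.99
406,319296,214556,1358.79
407,338950,230975,1347.7
408,358306,247964,1336.74
409,377146,265467,1325.88
410,395248,283415,1315.15
411,412386,301728,1304.52
412,428336,320311,1294.01
413,442887,339055,1283.6
414,455842,357834,1273.31
415,467028,376503,1263.12
416,476299,394899,1253.03
417,483546,412840,1243.06
418,488695,430126,1233.18
419,491713,446541,1223.41
420,492609,461858,1213.73
421,491432,475844,1204.16
422,488267,488267,1194.69
423,483229,498903,1185.31
424,476462,507544,1176.02
425,468126,514007,1166.83
426,458396,518141,1157.74
427,447448,519833,1148.73
428,435461,519013,1139.82
429,422607,515656,1131
430,409047,509785,1122.26
431,394932,501468,1113.61
432,380399,490816,1105.05
433,365571,477978,1096.58
434,350558,463139,1088.19
435,335456,446511,1079.88
436,320351,428325,1071.65
437,305316,408831,1063.51
438,290415,388287,1055.44
439,275704,366954,1047.46
440,261229,345091,1039.55
441,247031,322951,1031.72
442,233144,300774,1023.97
443,219596,278786,1016.29
444,206410,257195,1008.69
445,193606,236186,1001.16
446,181201,215923,993.708
447,169210,196543,986.325
448,157646,178158,979.012
449,146522,160855,971.77
450,135851,144694,964.598
451,125645,129710,957.494
452,115918,115918,950.458
453,106681,103308,943.489
454,97947.5,91855.2,936.587
455,89726.9,81517.7,929.75
456,82027.6,72242.2,922.977
457,74854.5,63966.1,916.269
458,68208.9,56620.5,909.624
459,62087.9,50133.3,903.041
460,56484.1,44430.9,896.521
461,51385.5,39440.7,890.061
462,46775.8,35092.3,883.662
463,42634.9,31318.6,877.322
464,38939.2,28057,871.042
465,35662.4,25249.3,864.82
466,32776.5,22842.3,858.655
467,30251.9,20787.7,852.548
468,28058.9,19042,846.497
469,26167.5,17566.3,840.501
470,24548.6,16325.9,834.561
471,23174.1,15290.5,828.675
472,22017.2,14433.1,822.843
473,21053.1,13730.2,817.064
474,20258.7,13161.4,811.338
475,19612.6,12709,805.664
476,19095.8,12357.7,800.042
477,18690.9,12094.7,794.47
478,18382.6,11908.9,788.949
479,18157.1,11791.1,783.478
480,18002.5,11733.7,778.056
481,17908.1,11730.3,772.682
482,17864.8,11776.1,767.357
483,17864.5,11867.1,762.079
484,17900.3,12000.3,756.848
485,17966.1,12173.7,751.664
486,18056.5,12385.8,746.526
487,18167.2,12636,741.434
488,18293.9,12924,736.387
489,18433.2,13250.1,731.384
490,18582,13614.7,726.425
491,18737.9,14018.7,721.51
492,18898.4,14463,716.639
493,19061.7,14948.7,711.809
494,19226.5,15476.6,707.022
495,19391.6,16047.5,702.277
496,19556.5,16662.1,697.573
497,19721,17320.6,692.911
498,19885.3,18023,688.288
499,20050.2,18768.8,683.706
500,20216.8,19557.1,679.163
501,20386.7,20386.7,674.659
502,20561.7,21255.8,670.194
503,20744,22162.6,665.767
504,20936,23104.7,661.379
505,21139.9,24079.8,657.028
506,21358.2,25085.4,652.714
507,21593.1,26118.8,648.436
508,21846.7,27177.6,644.196
509,22120.8,28259.4,639.991
510,22416.9,29361.9,635.822
511,22736.1,30483,631.688
512,23079.4,31620.6,627.588
513,23447.1,32773.1,623.524
514,23839.4,33938.8,619.493
515,24256,35116.1,615.497
516,24696.6,36303.6,611.534
517,25160.3,37499.9,607.604
518,25646.1,38703.7,603.706
519,26152.9,39913.7,599.842
520,26679.3,41128.4,596.009
521,27223.8,42346.4,592.208
522,27784.6,43566.4,588.439
523,28360.2,44786.5,584.7
524,28948.5,46005.3,580.993
525,29547.8,47221,577.316
526,30156.1,48431.6,573.669
527,30771.4,49635.3,570.052
528,31391.7,50829.8,566.465
529,32014.9,52013.1,562.907
530,32638.9,53182.7,559.378
531,33261.8,54336.5,555.878
532,33881.5,55471.9,552.406
533,34496,56586.4,548.962
534,35103.2,57677.3,545.546
535,35701.2,58742.2,542.158
536,36288,59778.3,538.797
537,36861.9,60783,535.463
538,37420.8,61753.5,532.156
539,37963.2,62687.2,528.875
540,38487.2,63581.4,525.621
541,38991.3,64433.4,522.393
542,39474,65240.7,519.19
543,39933.8,66000.8,516.013
544,40369.5,66711,512.861
545,40779.8,67369.1,509.734
546,41163.8,67972.6,506.632
547,41520.4,68519.4,503.554
548,41849,69007.2,500.501
549,42149,69434,497.471
550,42419.9,69798,494.466
551,42661.4,70097.2,491.484
552,42873.5,70330,488.525
553,43056.3,70494.8,485.589
554,43210.2,70590,482.677
555,43335.6,70614.4,479.787
556,43433.4,70566.6,476.919
557,43504.4,70445.6,474.074
558,43549.8,70250.4,471.251
559,43571.1,69980,468.449
560,43569.8,69633.8,465.67
561,43547.6,69211,462.911
562,43506.7,68711.2,460.174
563,43449.1,68133.9,457.458
564,43377.1,67479.1,454.762
565,43293,66746.8,452.088
566,43199.3,65937,449.433
567,43098.5,65050.4,446.799
568,42992.9,64087.6,444.185
569,42884.7,63049.8,441.591
570,42776,61938.7,439.016
571,42668.5,60756.2,436.461
572,42563.4,59505.1,433.925
573,42461.7,58188.7,431.409
574,42363.4,56810.9,428.911
575,42268.1,55376.8,426.432
576,42174.6,53891.8,423.972
577,42080.8,52362.6,421.53
578,41984.1,50796.4,419.106
579,41880.9,49201.5,416.701
580,41767.1,47586.4,414.313
581,41638.1,45960.3,411.943
582,41489,44332.7,409.591
583,41314.8,42713.1,407.256
584,41110.7,41110.7,404.939
585,40872.4,39534.3,402.638
586,40595.9,37991.8,400.355
587,40278.4,36490.4,398.088
588,39917.8,35036.1,395.838
589,39513,33633.7,393.604
590,39064.2,32286.8,391.387
591,38572.3,30997.9,389.186
592,38039.4,29768.3,387.002
593,37468.4,28598.2,384.833
594,36862.6,27487.2,382.679
595,36226.2,26434,380.542
596,35563.3,25436.8,378.42
597,34878.6,24493.4,376.313
598,34176.7,23601.3,374.222
599,33462.1,22757.9,372.145
600,32739.2,21960.6,370.084
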