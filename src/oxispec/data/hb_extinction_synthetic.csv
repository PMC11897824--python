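# Synthetic reconstruction of the standard oxy/deoxy haemoglobin molar
# extinction compilations (monotone interpolation through literature
# anchor values; approximate, intended for uncalibrated StO2 work).
# Units: L mol^-1 cm^-1. Substitute a tabulated dataset for calibrated use.
wavelength_nm,eps_hbo2,eps_hb
500.0,21000.0,20800.0
501.0,21569.0,21291.0
502.0,22136.1,21784.1
503.0,22701.1,22279.1
504.0,23264.2,22776.2
505.0,23825.2,23275.2
506.0,24384.3,23776.3
507.0,24941.3,24279.3
508.0,25496.2,24784.3
509.0,26049.1,25291.2
510.0,26600.0,25800.0
511.0,27140.0,26306.5
512.0,27664.4,26808.5
513.0,28179.1,27308.6
514.0,28689.7,27809.9
515.0,29202.4,28315.0
516.0,29722.8,28827.0
517.0,30257.0,29348.6
518.0,30810.6,29882.8
519.0,31389.7,30432.3
520.0,32000.0,31000.0
521.0,32630.4,31589.3
522.0,33270.0,32199.9
523.0,33925.3,32828.7
524.0,34603.0,33472.9
525.0,35309.3,34129.6
526.0,36050.9,34796.0
527.0,36834.3,35469.1
528.0,37666.0,36146.1
529.0,38552.3,36824.0
530.0,39500.0,37500.0
531.0,40584.9,38176.7
532.0,41838.0,38858.8
533.0,43198.8,39546.1
534.0,44606.4,40238.6
535.0,46000.0,40936.3
536.0,47530.6,41639.0
537.0,49240.2,42346.8
538.0,50904.4,43059.6
539.0,52299.1,43777.4
540.0,53200.0,44500.0
541.0,53744.8,45252.1
542.0,54000.0,46044.7
543.0,53605.5,46857.3
544.0,52614.8,47669.2
545.0,51316.6,48459.9
546.0,50000.0,49209.0
547.0,48589.6,49895.9
548.0,46903.9,50500.0
549.0,45072.5,51065.5
550.0,43224.9,51628.4
551.0,41490.9,52156.0
552.0,40000.0,52615.6
553.0,38689.5,52974.5
554.0,37456.3,53200.0
555.0,36370.1,53337.0
556.0,35500.0,53400.0
557.0,34740.7,53320.4
558.0,34030.6,53112.8
559.0,33505.2,52823.8
560.0,33300.0,52500.0
561.0,33397.0,52083.6
562.0,33658.7,51512.9
563.0,34041.1,50828.5
564.0,34500.0,50071.1
565.0,35254.6,49281.4
566.0,36482.4,48500.0
567.0,38077.1,47703.8
568.0,39932.5,46848.8
569.0,41942.2,45944.4
570.0,44000.0,45000.0
571.0,46600.8,44004.5
572.0,49805.8,42951.5
573.0,52857.9,41857.9
574.0,55000.0,40740.3
575.0,56415.5,39615.4
576.0,57541.1,38500.0
577.0,58000.0,37389.7
578.0,56661.2,36269.5
579.0,53544.5,35139.4
580.0,50000.0,34000.0
581.0,46064.7,32835.8
582.0,41314.5,31644.4
583.0,36407.0,30445.5
584.0,32000.0,29258.7
585.0,28111.2,28103.7
586.0,24400.8,27000.0
587.0,20990.0,25952.2
588.0,18000.0,24943.9
589.0,15303.5,23963.7
590.0,12798.4,23000.0
591.0,10644.1,22038.0
592.0,9000.0,21078.4
593.0,7777.6,20133.1
594.0,6759.6,19213.7
595.0,5911.8,18332.1
596.0,5200.0,17500.0
597.0,4570.5,16716.5
598.0,4009.9,15972.5
599.0,3544.3,15267.2
600.0,3200.0,14600.0
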