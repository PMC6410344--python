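wavelength_nm,n,k
400.0,1.470116,0.000000
410.0,1.469066,0.000000
420.0,1.468094,0.000000
430.0,1.467190,0.000000
440.0,1.466350,0.000000
450.0,1.465566,0.000000
460.0,1.464833,0.000000
470.0,1.464146,0.000000
480.0,1.463502,0.000000
490.0,1.462897,0.000000
500.0,1.462326,0.000000
510.0,1.461789,0.000000
520.0,1.461280,0.000000
530.0,1.460799,0.000000
540.0,1.460344,0.000000
550.0,1.459911,0.000000
560.0,1.459500,0.000000
570.0,1.459108,0.000000
580.0,1.458735,0.000000
590.0,1.458378,0.000000
600.0,1.458038,0.000000
610.0,1.457712,0.000000
620.0,1.457399,0.000000
630.0,1.457100,0.000000
640.0,1.456812,0.000000
650.0,1.456535,0.000000
660.0,1.456268,0.000000
670.0,1.456011,0.000000
680.0,1.455764,0.000000
690.0,1.455524,0.000000
700.0,1.455292,0.000000
710.0,1.455068,0.000000
720.0,1.454851,0.000000
730.0,1.454640,0.000000
740.0,1.454436,0.000000
750.0,1.454237,0.000000
760.0,1.454043,0.000000
770.0,1.453855,0.000000
780.0,1.453671,0.000000
790.0,1.453492,0.000000
800.0,1.453317,0.000000
810.0,1.453146,0.000000
820.0,1.452979,0.000000
830.0,1.452816,0.000000
840.0,1.452655,0.000000
850.0,1.452498,0.000000
860.0,1.452344,0.000000
870.0,1.452193,0.000000
880.0,1.452044,0.000000
890.0,1.451898,0.000000
900.0,1.451754,0.000000
910.0,1.451612,0.000000
920.0,1.451473,0.000000
930.0,1.451335,0.000000
940.0,1.451199,0.000000
950.0,1.451065,0.000000
960.0,1.450933,0.000000
970.0,1.450802,0.000000
980.0,1.450672,0.000000
990.0,1.450544,0.000000
1000.0,1.450417,0.000000
1010.0,1.450292,0.000000
1020.0,1.450167,0.000000
1030.0,1.450044,0.000000
1040.0,1.449921,0.000000
1050.0,1.449800,0.000000
1060.0,1.449679,0.000000
1070.0,1.449559,0.000000
1080.0,1.449440,0.000000
1090.0,1.449321,0.000000
1100.0,1.449204,0.000000
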