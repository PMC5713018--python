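# pure seawater absorption aw and backscatter bbw (m-1), 5-nm grid
lambda_nm	aw	bbw
400	0.00663	0.0038
405	0.00568	0.00360145
410	0.00473	0.00341552
415	0.004635	0.00324127
420	0.00454	0.00307784
425	0.004745	0.00292444
430	0.00495	0.00278035
435	0.00565	0.0026449
440	0.00635	0.00251749
445	0.007785	0.00239755
450	0.00922	0.00228457
455	0.009505	0.00217808
460	0.00979	0.00207763
465	0.010195	0.00198283
470	0.0106	0.0018933
475	0.01165	0.0018087
480	0.0127	0.0017287
485	0.01385	0.00165302
490	0.015	0.00158138
495	0.0177	0.00151352
500	0.0204	0.00144921
505	0.02645	0.00138824
510	0.0325	0.00133039
515	0.0367	0.00127549
520	0.0409	0.00122334
525	0.04215	0.0011738
530	0.0434	0.00112671
535	0.0454	0.00108192
540	0.0474	0.0010393
545	0.05195	0.000998734
550	0.0565	0.000960099
555	0.0592	0.000923288
560	0.0619	0.000888199
565	0.0657	0.000854739
570	0.0695	0.000822817
575	0.07955	0.000792351
580	0.0896	0.000763262
585	0.11235	0.000735478
590	0.1351	0.000708928
595	0.17875	0.000683549
600	0.2224	0.000659279
605	0.2434	0.000636062
610	0.2644	0.000613844
615	0.26995	0.000592574
620	0.2755	0.000572204
625	0.28355	0.000552689
630	0.2916	0.000533988
635	0.3012	0.00051606
640	0.3108	0.000498868
645	0.3254	0.000482375
650	0.34	0.000466549
655	0.375	0.000451357
660	0.41	0.00043677
665	0.4245	0.000422759
670	0.439	0.000409298
675	0.452	0.000396361
680	0.465	0.000383923
685	0.4905	0.000371963
690	0.516	0.000360458
695	0.57	0.000349388
700	0.624	0.000338734
705	0.7255	0.000328478
710	0.827	0.000318601
715	1.029	0.000309087
720	1.231	0.000299921
725	1.515	0.000291087
730	1.799	0.000282571
735	2.0895	0.00027436
740	2.38	0.000266441
745	2.425	0.000258802
750	2.47	0.000251431
755	2.51	0.000244316
760	2.55	0.000237448
765	2.53	0.000230816
770	2.51	0.00022441
775	2.435	0.000218222
780	2.36	0.000212243
785	2.26	0.000206465
790	2.16	0.000200879
795	2.115	0.000195477
800	2.07	0.000190254
805	2.2	0.000185202
810	2.33	0.000180313
815	2.61	0.000175583
820	2.89	0.000171004
825	3.265	0.000166572
830	3.64	0.00016228
835	4.045	0.000158124
840	4.45	0.000154098
845	4.52	0.000150197
850	4.59	0.000146418
855	4.6	0.000142754
860	4.61	0.000139203
865	4.855	0.00013576
870	5.1	0.000132422
875	5.515	0.000129184
880	5.93	0.000126043
885	6.615	0.000122995
890	7.3	0.000120038
895	7.15	0.000117168
900	7	0.000114381
905	7.5	0.000111676
910	8	0.00010905
915	9.5	0.000106499
920	11	0.000104021
925	14	0.000101613
930	17	9.92742e-05
935	21.5	9.70011e-05
940	26	9.47917e-05
945	29	9.2644e-05
950	32	9.05559e-05
955	36	8.85255e-05
960	40	8.65508e-05
965	42.5	8.46301e-05
970	45	8.27616e-05
975	44	8.09437e-05
980	43	7.91746e-05
985	42	7.7453e-05
990	41	7.57772e-05
995	38.5	7.41459e-05
1000	36	7.25576e-05
1005	33.5	7.1011e-05
1010	31	6.95047e-05
1015	28.5	6.80377e-05
1020	26	6.66086e-05
1025	24	6.52162e-05
1030	22	6.38596e-05
1035	20.5	6.25375e-05
1040	19	6.1249e-05
1045	18	5.9993e-05
1050	17	5.87686e-05
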