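# phytoplankton absorption shape coefficients (dimensionless), 5-nm grid
lambda_nm	a0	a1
400	0.6843	0.0205
405	0.73125	0.0167
410	0.7782	0.0129
415	0.82095	0.00945
420	0.8637	0.006
425	0.912	0.004
430	0.9603	0.002
435	0.98015	0.001
440	1	0
445	0.9817	0.003
450	0.9634	0.006
455	0.94725	0.00845
460	0.9311	0.0109
465	0.9004	0.0133
470	0.8697	0.0157
475	0.82935	0.01545
480	0.789	0.0152
485	0.7724	0.0204
490	0.7558	0.0256
495	0.74455	0.04075
500	0.7333	0.0559
505	0.7122	0.0712
510	0.6911	0.0865
515	0.6619	0.0923
520	0.6327	0.0981
525	0.6004	0.0975
530	0.5681	0.0969
535	0.53635	0.09345
540	0.5046	0.09
545	0.4654	0.08405
550	0.4262	0.0781
555	0.38475	0.072
560	0.3433	0.0659
565	0.31915	0.06295
570	0.295	0.06
575	0.2867	0.05905
580	0.2784	0.0581
585	0.26895	0.05605
590	0.2595	0.054
595	0.2492	0.05175
600	0.2389	0.0495
605	0.2567	0.05365
610	0.2745	0.0578
615	0.2971	0.0626
620	0.3197	0.0674
625	0.32	0.0667
630	0.3203	0.066
635	0.318	0.06535
640	0.3157	0.0647
645	0.30785	0.06595
650	0.3	0.0672
655	0.291	0.06245
660	0.282	0.0577
665	0.2868	0.0535
670	0.2916	0.0493
675	0.2687	0.04725
680	0.2458	0.0452
685	0.20205	0.0386
690	0.1583	0.032
695	0.1278	0.0246
700	0.0973	0.0172
705	0.07505	0.01325
710	0.0528	0.0093
715	0.0414	0.0073
720	0.03	0.0053
725	0	0
730	0	0
735	0	0
740	0	0
745	0	0
750	0	0
755	0	0
760	0	0
765	0	0
770	0	0
775	0	0
780	0	0
785	0	0
790	0	0
795	0	0
800	0	0
805	0	0
810	0	0
815	0	0
820	0	0
825	0	0
830	0	0
835	0	0
840	0	0
845	0	0
850	0	0
855	0	0
860	0	0
865	0	0
870	0	0
875	0	0
880	0	0
885	0	0
890	0	0
895	0	0
900	0	0
905	0	0
910	0	0
915	0	0
920	0	0
925	0	0
930	0	0
935	0	0
940	0	0
945	0	0
950	0	0
955	0	0
960	0	0
965	0	0
970	0	0
975	0	0
980	0	0
985	0	0
990	0	0
995	0	0
1000	0	0
1005	0	0
1010	0	0
1015	0	0
1020	0	0
1025	0	0
1030	0	0
1035	0	0
1040	0	0
1045	0	0
1050	0	0
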