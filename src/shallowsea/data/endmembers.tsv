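# synthetic benthic endmember albedo spectra (not measured data)
lambda_nm	sand	algae	sediment
400	0.38284	0.03000	0.08318
405	0.38446	0.03000	0.08329
410	0.38614	0.03000	0.08341
415	0.38790	0.03000	0.08353
420	0.38972	0.03001	0.08365
425	0.39161	0.03001	0.08377
430	0.39357	0.03003	0.08390
435	0.39561	0.03005	0.08404
440	0.39771	0.03010	0.08417
445	0.39990	0.03019	0.08431
450	0.40215	0.03035	0.08445
455	0.40448	0.03062	0.08460
460	0.40689	0.03106	0.08475
465	0.40936	0.03178	0.08490
470	0.41192	0.03289	0.08506
475	0.41454	0.03457	0.08522
480	0.41724	0.03703	0.08538
485	0.42000	0.04052	0.08554
490	0.42283	0.04530	0.08571
495	0.42574	0.05165	0.08588
500	0.42870	0.05980	0.08606
505	0.43173	0.06990	0.08624
510	0.43481	0.08194	0.08642
515	0.43795	0.09578	0.08660
520	0.44114	0.11101	0.08678
525	0.44439	0.12704	0.08697
530	0.44767	0.14306	0.08716
535	0.45100	0.15812	0.08736
540	0.45436	0.17120	0.08755
545	0.45775	0.18135	0.08775
550	0.46117	0.18779	0.08795
555	0.46461	0.19000	0.08815
560	0.46806	0.18779	0.08835
565	0.47153	0.18135	0.08855
570	0.47500	0.17120	0.08876
575	0.47847	0.15812	0.08896
580	0.48194	0.14307	0.08917
585	0.48539	0.12705	0.08938
590	0.48883	0.11102	0.08958
595	0.49225	0.09579	0.08979
600	0.49564	0.08196	0.09000
605	0.49900	0.06992	0.09021
610	0.50233	0.05982	0.09042
615	0.50561	0.05165	0.09062
620	0.50886	0.04523	0.09083
625	0.51205	0.04027	0.09104
630	0.51519	0.03642	0.09124
635	0.51827	0.03328	0.09145
640	0.52130	0.03049	0.09165
645	0.52426	0.02772	0.09185
650	0.52717	0.02485	0.09205
655	0.53000	0.02197	0.09225
660	0.53276	0.01945	0.09245
665	0.53546	0.01794	0.09264
670	0.53808	0.01821	0.09284
675	0.54064	0.02108	0.09303
680	0.54311	0.02721	0.09322
685	0.54552	0.03715	0.09340
690	0.54785	0.05131	0.09358
695	0.55010	0.07005	0.09376
700	0.55229	0.09364	0.09394
705	0.55439	0.12195	0.09412
710	0.55643	0.15412	0.09429
715	0.55839	0.18831	0.09446
720	0.56028	0.22198	0.09462
725	0.56210	0.25264	0.09478
730	0.56386	0.27855	0.09494
735	0.56554	0.29908	0.09510
740	0.56716	0.31454	0.09525
745	0.56871	0.32571	0.09540
750	0.57020	0.33357	0.09555
755	0.57163	0.33898	0.09569
760	0.57299	0.34265	0.09583
765	0.57430	0.34511	0.09596
770	0.57556	0.34676	0.09610
775	0.57675	0.34786	0.09623
780	0.57790	0.34858	0.09635
785	0.57899	0.34907	0.09647
790	0.58004	0.34938	0.09659
795	0.58104	0.34959	0.09671
800	0.58199	0.34973	0.09682
805	0.58289	0.34982	0.09693
810	0.58376	0.34988	0.09704
815	0.58458	0.34992	0.09714
820	0.58537	0.34995	0.09724
825	0.58611	0.34997	0.09734
830	0.58682	0.34998	0.09744
835	0.58750	0.34999	0.09753
840	0.58814	0.34999	0.09762
845	0.58876	0.34999	0.09770
850	0.58934	0.35000	0.09779
855	0.58989	0.35000	0.09787
860	0.59042	0.35000	0.09794
865	0.59091	0.35000	0.09802
870	0.59139	0.35000	0.09809
875	0.59184	0.35000	0.09816
880	0.59227	0.35000	0.09823
885	0.59267	0.35000	0.09830
890	0.59306	0.35000	0.09836
895	0.59342	0.35000	0.09842
900	0.59377	0.35000	0.09848
905	0.59410	0.35000	0.09854
910	0.59441	0.35000	0.09860
915	0.59471	0.35000	0.09865
920	0.59499	0.35000	0.09870
925	0.59525	0.35000	0.09875
930	0.59550	0.35000	0.09880
935	0.59574	0.35000	0.09884
940	0.59597	0.35000	0.09889
945	0.59618	0.35000	0.09893
950	0.59639	0.35000	0.09897
955	0.59658	0.35000	0.09901
960	0.59676	0.35000	0.09905
965	0.59693	0.35000	0.09909
970	0.59710	0.35000	0.09912
975	0.59725	0.35000	0.09916
980	0.59740	0.35000	0.09919
985	0.59754	0.35000	0.09922
990	0.59767	0.35000	0.09925
995	0.59780	0.35000	0.09928
1000	0.59791	0.35000	0.09931
1005	0.59803	0.35000	0.09934
1010	0.59813	0.35000	0.09936
1015	0.59823	0.35000	0.09939
1020	0.59833	0.35000	0.09941
1025	0.59842	0.35000	0.09944
1030	0.59850	0.35000	0.09946
1035	0.59858	0.35000	0.09948
1040	0.59866	0.35000	0.09950
1045	0.59873	0.35000	0.09952
1050	0.59880	0.35000	0.09954
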