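asv_id	dataset	taxon	genus	reads
ASV_LGC_00001	LGC	Micromonas bravo clade B2	Micromonas	28810
ASV_LGC_00002	LGC	Ostreococcus lucimarinus	Ostreococcus	22885
ASV_LGC_00003	LGC	Ostreococcus clade E	Ostreococcus	22720
ASV_LGC_00004	LGC	Bathycoccus prasinos	Bathycoccus	16750
ASV_LGC_00005	LGC	Micromonas commoda clade A2	Micromonas	10787
ASV_LGC_00006	LGC	Ostreococcus clade B	Ostreococcus	6207
ASV_LGC_00007	LGC	Micromonas commoda clade A1	Micromonas	5465
ASV_LGC_00008	LGC	Micromonas bravo clade B1	Micromonas	5459
ASV_LGC_00009	LGC	Micromonas clade B5	Micromonas	5251
ASV_LGC_00010	LGC	Mantoniella squamata	Mantoniella	4500
ASV_LGC_00011	LGC	Mantoniella clade B	Mantoniella	4070
ASV_LGC_00012	LGC	Ostreococcus tauri	Ostreococcus	3558
ASV_LGC_00013	LGC	Ostreococcus tauri	Ostreococcus	3288
ASV_LGC_00014	LGC	Micromonas polaris	Micromonas	2200
ASV_LGC_00015	LGC	Micromonas clade B4	Micromonas	1616
ASV_LGC_00016	LGC	Micromonas pusilla	Micromonas	1259
ASV_LGC_00017	LGC	Micromonas clade B3	Micromonas	1096
ASV_LGC_00018	LGC	Ostreococcus tauri	Ostreococcus	1061
ASV_LGC_00019	LGC	Micromonas clade B5	Micromonas	1045
ASV_LGC_00022	LGC	Ostreococcus mediterraneus	Ostreococcus	369
ASV_LGC_00023	LGC	Ostreococcus clade E	Ostreococcus	277
ASV_LGC_00024	LGC	Ostreococcus mediterraneus	Ostreococcus	248
ASV_LGC_00025	LGC	Ostreococcus lucimarinus	Ostreococcus	234
ASV_LW_00001	LW	Ostreococcus mediterraneus	Ostreococcus	67761
ASV_LW_00002	LW	Ostreococcus clade E	Ostreococcus	37318
ASV_LW_00003	LW	Micromonas polaris	Micromonas	35194
ASV_LW_00004	LW	Mantoniella squamata	Mantoniella	25692
ASV_LW_00005	LW	Bathycoccus prasinos	Bathycoccus	20779
ASV_LW_00006	LW	Micromonas bravo clade B2	Micromonas	20153
ASV_LW_00007	LW	Micromonas commoda clade A2	Micromonas	14869
ASV_LW_00008	LW	Ostreococcus tauri	Ostreococcus	13511
ASV_LW_00009	LW	Ostreococcus lucimarinus	Ostreococcus	7310
ASV_LW_00010	LW	Ostreococcus tauri	Ostreococcus	5640
ASV_LW_00011	LW	Micromonas pusilla	Micromonas	2806
ASV_LW_00012	LW	Micromonas commoda clade A1	Micromonas	2610
ASV_LW_00013	LW	Micromonas bravo clade B1	Micromonas	2357
ASV_LW_00014	LW	Micromonas clade B3	Micromonas	1862
ASV_LW_00015	LW	Micromonas clade B4	Micromonas	1078
ASV_LW_00016	LW	Mantoniella clade B	Mantoniella	935
ASV_LW_00017	LW	Ostreococcus tauri	Ostreococcus	908
ASV_LW_00018	LW	Mantoniella clade A	Mantoniella	841
ASV_LW_00020	LW	Micromonas polaris	Micromonas	668
ASV_LW_00021	LW	Micromonas clade B5	Micromonas	661
ASV_LW_00022	LW	Micromonas commoda clade A2	Micromonas	462
ASV_LW_00024	LW	Ostreococcus clade B	Ostreococcus	366
ASV_LW_00027	LW	Micromonas bravo clade B1	Micromonas	205
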