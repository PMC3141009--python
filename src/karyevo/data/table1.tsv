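centromere	species	copy	chrom	flags	notation
CEN1	Saccharomyces_cerevisiae	1	3	strand_plus	3+
CEN1	Saccharomyces_cerevisiae	2	14	strand_plus	14+
CEN1	Saccharomyces_bayanus	1	3	-	3
CEN1	Saccharomyces_bayanus	2	14	-	14
CEN1	Candida_glabrata	1	2	translocation_at_cen	2r
CEN1	Candida_glabrata	2	-	lost	X
CEN1	Vanderwaltozyma_polyspora	1	s1050	-	s1050
CEN1	Vanderwaltozyma_polyspora	2	-	lost,translocation_at_cen	Xr
CEN1	Zygosaccharomyces_rouxii	1	5	-	5
CEN1	Kluyveromyces_lactis	1	1	translocation_at_cen	1r
CEN1	Ashbya_gossypii	1	1	-	1
CEN1	Lachancea_kluyveri	1	4	orientation_change	4*
CEN1	Lachancea_thermotolerans	1	8	-	8
CEN1	Lachancea_waltii	1	s0	-	s0
CEN2	Saccharomyces_cerevisiae	1	8	strand_minus	8-
CEN2	Saccharomyces_cerevisiae	2	11	strand_minus	11-
CEN2	Saccharomyces_bayanus	1	8	-	8
CEN2	Saccharomyces_bayanus	2	11	-	11
CEN2	Candida_glabrata	1	11	inversion_at_cen	11i
CEN2	Candida_glabrata	2	-	lost	X
CEN2	Vanderwaltozyma_polyspora	1	s1056	orientation_change	s1056*
CEN2	Vanderwaltozyma_polyspora	2	s1018	-	s1018
CEN2	Zygosaccharomyces_rouxii	1	-	lost	X
CEN2	Kluyveromyces_lactis	1	2	-	2
CEN2	Ashbya_gossypii	1	2	-	2
CEN2	Lachancea_kluyveri	1	1	orientation_change	1*
CEN2	Lachancea_thermotolerans	1	4	orientation_change	4*
CEN2	Lachancea_waltii	1	s26	orientation_change	s26*
CEN3	Saccharomyces_cerevisiae	1	2	strand_plus	2+
CEN3	Saccharomyces_cerevisiae	2	4	strand_plus	4+
CEN3	Saccharomyces_bayanus	1	2	-	2
CEN3	Saccharomyces_bayanus	2	4	-	4
CEN3	Candida_glabrata	1	3	orientation_change	3*
CEN3	Candida_glabrata	2	13	-	13
CEN3	Vanderwaltozyma_polyspora	1	s1036	-	s1036
CEN3	Vanderwaltozyma_polyspora	2	s1045	-	s1045
CEN3	Zygosaccharomyces_rouxii	1	1	-	1
CEN3	Kluyveromyces_lactis	1	-	lost	X
CEN3	Ashbya_gossypii	1	5	-	5
CEN3	Lachancea_kluyveri	1	3	-	3
CEN3	Lachancea_thermotolerans	1	7	orientation_change	7*
CEN3	Lachancea_waltii	1	s27	orientation_change	s27*
CEN4	Saccharomyces_cerevisiae	1	1	strand_plus	1+
CEN4	Saccharomyces_cerevisiae	2	7	strand_minus	7-
CEN4	Saccharomyces_bayanus	1	1	-	1
CEN4	Saccharomyces_bayanus	2	7	-	7
CEN4	Candida_glabrata	1	1	inversion_at_cen	1i
CEN4	Candida_glabrata	2	7	translocation_at_cen	7r
CEN4	Vanderwaltozyma_polyspora	1	s1062	-	s1062
CEN4	Vanderwaltozyma_polyspora	2	-	lost	X
CEN4	Zygosaccharomyces_rouxii	1	7	-	7
CEN4	Kluyveromyces_lactis	1	3	orientation_change	3*
CEN4	Ashbya_gossypii	1	6	-	6
CEN4	Lachancea_kluyveri	1	8	orientation_change	8*
CEN4	Lachancea_thermotolerans	1	5	orientation_change	5*
CEN4	Lachancea_waltii	1	s47	orientation_change	s47*
CEN5	Saccharomyces_cerevisiae	1	10	strand_minus	10-
CEN5	Saccharomyces_cerevisiae	2	12	strand_minus	12-
CEN5	Saccharomyces_bayanus	1	10	-	10
CEN5	Saccharomyces_bayanus	2	12	-	12
CEN5	Candida_glabrata	1	4	-	4
CEN5	Candida_glabrata	2	-	lost	X
CEN5	Vanderwaltozyma_polyspora	1	s534	-	s534
CEN5	Vanderwaltozyma_polyspora	2	s2002	-	s2002
CEN5	Zygosaccharomyces_rouxii	1	2	-	2
CEN5	Kluyveromyces_lactis	1	6	translocation_at_cen	6r
CEN5	Ashbya_gossypii	1	-	lost,translocation_at_cen	Xr
CEN5	Lachancea_kluyveri	1	7	orientation_change	7*
CEN5	Lachancea_thermotolerans	1	2	orientation_change	2*
CEN5	Lachancea_waltii	1	s33	orientation_change	s33*
CEN6	Saccharomyces_cerevisiae	1	13	strand_plus	13+
CEN6	Saccharomyces_cerevisiae	2	15	strand_minus	15-
CEN6	Saccharomyces_bayanus	1	13	-	13
CEN6	Saccharomyces_bayanus	2	15	-	15
CEN6	Candida_glabrata	1	5	-	5
CEN6	Candida_glabrata	2	9	possible_orientation_change,translocation_at_cen	9?r
CEN6	Vanderwaltozyma_polyspora	1	s1032	-	s1032
CEN6	Vanderwaltozyma_polyspora	2	s1037	-	s1037
CEN6	Zygosaccharomyces_rouxii	1	3	-	3
CEN6	Kluyveromyces_lactis	1	-	lost	X
CEN6	Ashbya_gossypii	1	3	-	3
CEN6	Lachancea_kluyveri	1	5	-	5
CEN6	Lachancea_thermotolerans	1	3	-	3
CEN6	Lachancea_waltii	1	s56	-	s56
CEN7	Saccharomyces_cerevisiae	1	5	strand_plus	5+
CEN7	Saccharomyces_cerevisiae	2	9	strand_plus	9+
CEN7	Saccharomyces_bayanus	1	5	-	5
CEN7	Saccharomyces_bayanus	2	9	-	9
CEN7	Candida_glabrata	1	8	translocation_at_cen	8r
CEN7	Candida_glabrata	2	10	-	10
CEN7	Vanderwaltozyma_polyspora	1	s499	-	s499
CEN7	Vanderwaltozyma_polyspora	2	s312	-	s312
CEN7	Zygosaccharomyces_rouxii	1	4	-	4
CEN7	Kluyveromyces_lactis	1	4	orientation_change	4*
CEN7	Ashbya_gossypii	1	4	-	4
CEN7	Lachancea_kluyveri	1	6	-	6
CEN7	Lachancea_thermotolerans	1	6	-	6
CEN7	Lachancea_waltii	1	s55	-	s55
CEN8	Saccharomyces_cerevisiae	1	6	strand_plus	6+
CEN8	Saccharomyces_cerevisiae	2	16	strand_plus	16+
CEN8	Saccharomyces_bayanus	1	6	-	6
CEN8	Saccharomyces_bayanus	2	16	-	16
CEN8	Candida_glabrata	1	6	-	6
CEN8	Candida_glabrata	2	12	-	12
CEN8	Vanderwaltozyma_polyspora	1	s354	-	s354
CEN8	Vanderwaltozyma_polyspora	2	s1058	-	s1058
CEN8	Zygosaccharomyces_rouxii	1	6	-	6
CEN8	Kluyveromyces_lactis	1	5	orientation_change	5*
CEN8	Ashbya_gossypii	1	7	-	7
CEN8	Lachancea_kluyveri	1	2	-	2
CEN8	Lachancea_thermotolerans	1	1	-	1
CEN8	Lachancea_waltii	1	s23	-	s23
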