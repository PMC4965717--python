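index,enzyme,ec,kind,substrate_pattern,product_pattern,constraint,subst_min_struct,subst_max_struct,subst_na_branch,subst_na_struct,subst_na_residue,target_branch,target_na_branch,is_terminal_target,source_note
1,ManI,3.2.1.113,GH,(Ma2Ma,(Ma,~_Ma2Ma3Ma6,,,,,,,,,"printed product/constraint garbled ('(Ma ~*2Ma3(...Ma6)'); read as: remove a terminal alpha1-2 Man except the middle-arm one (the Ma2 on the Ma3 of the alpha6 arm), which only row 2 removes"
2,ManI,3.2.1.113,GH,Ma3(Ma2Ma3(Ma6)Ma6)Mb4,Ma3(Ma3(Ma6)Ma6)Mb4,,,,Ma2Ma3Mb4,,,,,,"printed substrate '(Ma3(Ma2Ma3(Ma6)Ma6)'; removes the middle-arm alpha1-2 Man once the alpha3 arm carries no alpha1-2 Man (substNABranch)"
3,ManII,3.2.1.114,GH,(Ma3(Ma6)Ma6,(Ma6Ma6,GNb2 |Ma3 & ~Gnbis,,,(Ma2M,,,,,,"substNABranch: ManII acts only after ManI trimming is complete (no terminal alpha1-2 Man left)"
4,ManII,3.2.1.114,GH,(Ma6Ma6,(Ma6,GNb2 |Ma3 & ~Gnbis,,,(Ma2M,Ma3Ma6Mb4GNb4GN,,,,,"substNABranch as row 3; substNAStruct: fires only after row 3 has removed the alpha1-3 Man of the alpha6 arm"
5,FUT8,2.4.1.68,GT,GNb4GN,GNb4(Fa6)GN,GNb2 |Ma3 & ~Gnbis & ~Ab,GNb2Ma3(GNb2Ma6)Mb4GNb4GN,,,,,,,,"substMinStruct: core fucosylation requires the biantennary agalacto core (both antennal GlcNAc present)"
6,MGAT1,2.4.1.101,GT,(Ma3(Ma3(Ma6)Ma6)Mb4,(GNb2Ma3(Ma3(Ma6)Ma6)Mb4,,,,,,,,,,"printed substrate '(Ma33(Ma3(Ma6)Ma6)Mb4' read as '(Ma3(Ma3(Ma6)Ma6)Mb4'; matched by embedding, so the hybrid pathway (action before full ManI trimming) is open"
7,MGAT2,2.4.1.143,GT,(Ma6(GNb2Ma3)Mb4,(GNb2Ma6(GNb2Ma3)Mb4,,,,,,,,,,"printed substrate '(GNb2|Ma3(Ma6)Mb4' read as: terminal core alpha6-Man with GNb2 already on the alpha3 arm"
8,MGAT3,2.4.1.144,GT,GNb2Ma3Mb4,GNb2Ma3(GNb4)Mb4,~Ab & ~Gnbis,GNb2Ma3(GNb2Ma6)Mb4GNb4GN,,,,,,,,"printed as 'GNb2 |Ma3 -> GNb2 |Ma3(GNb4)': adds the bisecting GN beta1-4 to the core beta-Man; substMinStruct: bisection modeled on the biantennary core"
9,MGAT4,2.4.1.145,GT,(GNb2Ma3Mb4,(GNb2(GNb4)Ma3Mb4,~Gnbis,GNb2Ma3(GNb2Ma6)Mb4GNb4GN,,,,,,,,"substMinStruct: branching requires the prior MGAT2 product"
10,MGAT5,2.4.1.155,GT,(GNb2Ma6Mb4,(GNb2(GNb6)Ma6Mb4,~Gnbis,,,,,,,,,
11,iGnT,2.4.1.149,GT,(Ab4GN,(GNb3Ab4GN,~_Ma3 |Mb4,,,,,,,,,"extends poly-LacNAc on branches other than the core alpha3 arm"
12,b4GalT,2.4.1.38,GT,(GN,(Ab4GN,~Gnbis,GNb2Ma3(GNb2Ma6)Mb4GNb4GN,,,,,,,,"printed constraint '(~*GNb4)(...Ma6)Mb4' read as: no bisecting GlcNAc; substMinStruct: beta1-4 galactosylation modeled on complex-type (post-MGAT2) structures"
13,a3SiaT,2.4.99.6,GT,(Ab4GN,(NNa3Ab4GN,,,,,,,,,,
14,IGNT,2.4.1.150,GT,(Ab4GNb3Ab,(Ab4GNb3(GNb6)Ab,,,,,,,,,,
15,a6SiaT,2.4.99.1,GT,(Ab4GN,(NNa6Ab4GN,,,,,,,,,,
16,b3GalT1,2.4.1.62,GT,(GN,(Ab3GN,~Gnbis,,,,,,,,,"printed constraint '(~*GNb4)(...Ma6)Mb4' read as: no bisecting GlcNAc"
17,FUT3,2.4.1.65,GT,Ab3GNb,Ab3(Fa4)GNb,(Ab3* or (Fa2Ab3* or (NNa3Ab3*,,,NNa3Ab,,F,,,,"substNAResidue/substNABranch: Lewis-a fucosylation modeled on unfucosylated, unsialylated type-1 chains"
18,FUT3,2.4.1.65,GT,(...Ab4GNb,(Fa3(...Ab4)GNb,(*Ab4 or (*Fa2Ab4 or (*NNa3Ab4,,,,,,,,,
19,FUT1,2.4.1.69,GT,(Ab3GNb,(Fa2Ab3GNb,,,,,,F,,,,"substNAResidue: H-antigen synthesis modeled before any fucosylation"
20,FUT1,2.4.1.69,GT,(Ab4GNb,(Fa2Ab4GNb,,,,,,,,,,
21,a3FucT,2.4.1.152,GT,(...Ab4GNb,(Fa3(...Ab4)GNb,(*Ab4 or (*Fa2Ab4,,,,,,,,,
22,GalNAcT-A,2.4.1.40,GT,(Fa2Ab,(Fa2(ANa3)Ab,,,,,,,Ab4GN,,,"targetBranch: blood-group A antigen modeled on type-2 (Gal beta1-4) H chains"
23,GalT-B,2.4.1.37,GT,(Fa2Ab,(Fa2(Aa3)Ab,,,,,,,Ab4GN,,,"targetBranch: blood-group B antigen modeled on type-2 (Gal beta1-4) H chains"
24,b3GALT6,2.4.1.134,GT,Ab4GN,Ab3Ab4GN,,,,,,,,,,
25,b3GALT6,2.4.1.134,GT,Ab4A,Ab3Ab4A,,,,,,,,,,
26,c1GALT1,2.4.1.122,GT,AN,Ab3AN,,,,,,,,,,
27,st3galI,2.4.99.4,GT,(Ab3GN,(NNa3Ab3GN,,,,,,F,,,,"printed product '(NNa3Ab4GN' is inconsistent with the substrate '(Ab3GN'; read as sialylation of the beta1-3 Gal; substNAResidue: no action on fucosylated chains"
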