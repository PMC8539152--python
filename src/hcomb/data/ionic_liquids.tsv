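name	smiles	hc_exp
1,1,3,3-Tetramethylguanidinium nitrate	CN(C)C(=[NH2+])N(C)C.[O-][N+]([O-])=O	-3656.5
1-Butyl-1-methylpyrrolidinium dicyanamide	CCCC[N+]1(C)CCCC1.N#C[N-]C#N	-7244.8
1-Butyl-3-methylimidazolium chloride	CCCCn1cc[n+](C)c1.[Cl-]	-5232.3
1-Butyl-3-methylimidazolium dicyanoamide	CCCCn1cc[n+](C)c1.N#C[N-]C#N	-6273.9
1-Butyl-3-methylimidazolium nitrate	CCCCn1cc[n+](C)c1.[O-][N+]([O-])=O	-5013.2
1-Decyl-3-methylimidazolium bromide	CCCCCCCCCCn1cc[n+](C)c1.[Br-]	-9105.2
1-Dodecyl-3-methylimidazolium bromide	CCCCCCCCCCCCn1cc[n+](C)c1.[Br-]	-10406.0
1-Ethanol-3-methyl-imidazolium dicyanoamide	OCCn1cc[n+](C)c1.N#C[N-]C#N	-4793.0
1-Ethyl-3-methylimidazolium chloride	CCn1cc[n+](C)c1.[Cl-]	-3886.2
1-Ethyl-3-methylimidazolium dicyanamide	CCn1cc[n+](C)c1.N#C[N-]C#N	-4955.4
1-Ethyl-3-methylimidazolium nitrate	CCn1cc[n+](C)c1.[O-][N+]([O-])=O	-3697.5
1-Methyl-3-pentylimidazolium chloride	CCCCCn1cc[n+](C)c1.[Cl-]	-5904.3
1-Octyl-3-methylimidazolium bromide	CCCCCCCCn1cc[n+](C)c1.[Br-]	-7837.8
1-Tetradecyl-3-methylimidazolium bromide	CCCCCCCCCCCCCCn1cc[n+](C)c1.[Br-]	-11718.0
6,6-(Tetramethylene-3'-oxa)-7a-(nitroxymethyl)-3-oxoperhydroimidazo[1,5-c]oxazol-6-ium nitrate	O=C1OCC2(CO[N+](=O)[O-])N1C[N+]3(C2)CCOCC3.[O-][N+]([O-])=O	-5384.8
6,6-(Tetramethylene-3'-oxa)-7a-methyl-3-oxoperhydroimidazo[1,5-c]oxazol-6-ium nitrate	O=C1OCC2(C)N1C[N+]3(C2)CCOCC3.[O-][N+]([O-])=O	-5587.5
6,6-Pentamethylene-7a-(nitroxymethyl)-3-oxoperhydroimidazo[1,5-c]oxazol-6-ium nitrate	O=C1OCC2(CO[N+](=O)[O-])N1C[N+]3(C2)CCCCC3.[O-][N+]([O-])=O	-6166.4
Diethylammonium diethyldithiocarbamate	CC[NH2+]CC.CCN(CC)C(=S)[S-]	-7639.6
Diisobutylammonium diisobutyldithiocarbamate	CC(C)C[NH2+]CC(C)C.CC(C)CN(CC(C)C)C(=S)[S-]	-12891.0
Diisopropylammonium diisopropyldithiocarbamate	CC(C)[NH2+]C(C)C.CC(C)N(C(C)C)C(=S)[S-]	-10260.0
Dipropylammonium dipropyldithiocarbamate	CCC[NH2+]CCC.CCCN(CCC)C(=S)[S-]	-10252.0
N,N-Dimethylglycine bisulfate	C[NH+](C)CC(=O)O.OS(=O)(=O)[O-]	-2610.6
N,N-Dimethylglycine methyl ester bisulfate	C[NH+](C)CC(=O)OC.OS(=O)(=O)[O-]	-3323.2
N,N-Dimethylglycine methyl ester sulfate	C[NH+](C)CC(=O)OC.C[NH+](C)CC(=O)OC.[O-]S(=O)(=O)[O-]	-6765.2
N,N-Dimethylglycine sulfate	C[NH+](C)CC(=O)O.C[NH+](C)CC(=O)O.[O-]S(=O)(=O)[O-]	-5371.6
Tetraethylammonium nitrate	CC[N+](CC)(CC)CC.[O-][N+]([O-])=O	-5573.4
Tetramethylammonium nitrate	C[N+](C)(C)C.[O-][N+]([O-])=O	-2960.5
Tetra-n-butylammonium nitrate	CCCC[N+](CCCC)(CCCC)CCCC.[O-][N+]([O-])=O	-10841.0
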