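cefalexin	CC1=C(C(=O)[O-])N2C(=O)[C@H](NC(=O)[C@@H]([NH3+])c3ccccc3)[C@@H]2SC1
cefradine	CC1=C(C(=O)[O-])N2C(=O)[C@H](NC(=O)[C@@H]([NH3+])C3=CCC=CC3)[C@@H]2SC1
cefadroxil	CC1=C(C(=O)[O-])N2C(=O)[C@H](NC(=O)[C@@H]([NH3+])c3ccc(O)cc3)[C@@H]2SC1
cefaclor	[NH3+][C@H](C(=O)N[C@H]1C(=O)N2C(C(=O)[O-])=C(Cl)CS[C@@H]12)c1ccccc1
ceftizoxime	CO/N=C(\C(=O)N[C@H]1C(=O)N2C(C(=O)[O-])=CCS[C@@H]12)c1csc(N)n1
cefuroxime	CO/N=C(\C(=O)N[C@H]1C(=O)N2C(C(=O)[O-])=C(COC(N)=O)CS[C@@H]12)c1ccco1
cefoxitin	CO[C@@]1(NC(=O)Cc2cccs2)C(=O)N2C(C(=O)[O-])=C(COC(N)=O)CS[C@H]21
ceftezole	O=C(Cn1cnnn1)N[C@H]1C(=O)N2C(C(=O)[O-])=C(CSc3nncs3)CS[C@@H]12
cefazolin	Cc1nnc(SCC2=C(C(=O)[O-])N3C(=O)[C@H](NC(=O)Cn4cnnn4)[C@@H]3SC2)s1
cefotaxime	CO/N=C(\C(=O)N[C@H]1C(=O)N2C(C(=O)[O-])=C(COC(C)=O)CS[C@@H]12)c1csc(N)n1
cefathiamidine	CC(=O)OCC1=C(C(=O)[O-])N2C(=O)[C@H](NC(=O)CSC(NC(C)C)=[NH+]C(C)C)[C@@H]2SC1
flomoxef	CO[C@@]1(NC(=O)CSC(F)F)C(=O)N2C(C(=O)[O-])=C(CSc3nnnn3CCO)CO[C@H]21
cefmenoxime	CO/N=C(\C(=O)N[C@H]1C(=O)N2C(C(=O)[O-])=C(CSc3nnnn3C)CS[C@@H]12)c1csc(N)n1
cefpirome	CO/N=C(\C(=O)N[C@H]1C(=O)N2C(C(=O)[O-])=C(C[n+]3cccc4c3CCC4)CS[C@@H]12)c1csc(N)n1
cefminox	CO[C@@]1(NC(=O)CSC[C@@H]([NH3+])C(=O)[O-])C(=O)N2C(C(=O)[O-])=C(CSc3nnnn3C)CS[C@H]21
cefotiam	C[NH+](C)CCn1nnnc1SCC1=C(C(=O)[O-])N2C(=O)[C@H](NC(=O)Cc3csc(N)n3)[C@@H]2SC1
ceftazidime	CC(C)(O/N=C(\C(=O)N[C@H]1C(=O)N2C(C(=O)[O-])=C(C[n+]3ccccc3)CS[C@@H]12)c1csc(N)n1)C(=O)[O-]
cefodizime	CO/N=C(\C(=O)N[C@H]1C(=O)N2C(C(=O)[O-])=C(CSc3nc(C)c(CC(=O)[O-])s3)CS[C@@H]12)c1csc(N)n1
cefoperazone	CCN1CCN(C(=O)N[C@H](C(=O)N[C@H]2C(=O)N3C(C(=O)[O-])=C(CSc4nnnn4C)CS[C@@H]23)c2ccc(O)cc2)C(=O)C1=O
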