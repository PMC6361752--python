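drug_id,dose_mM,internal_conc_1e-5mM
cefalexin,0.28,1.01
cefalexin,1.0,5.48
cefalexin,2.0,16.83
cefradine,0.28,3.15
cefradine,1.0,8.93
cefradine,2.0,19.89
cefadroxil,0.28,1.32
cefadroxil,1.0,7.07
cefadroxil,2.0,12.55
cefaclor,0.28,1.01
cefaclor,1.0,3.43
cefaclor,2.0,9.49
ceftizoxime,0.28,1.17
ceftizoxime,1.0,3.70
ceftizoxime,2.0,13.15
ceftezole,0.28,3.95
ceftezole,1.0,7.08
ceftezole,2.0,12.96
cefuroxime,0.28,0.68
cefuroxime,1.0,1.55
cefuroxime,2.0,4.66
cefoxitin,0.28,2.22
cefoxitin,1.0,12.73
cefoxitin,2.0,18.39
cefazolin,0.28,8.56
cefazolin,1.0,13.95
cefazolin,2.0,14.19
cefotaxime,0.28,0.27
cefotaxime,1.0,0.75
cefotaxime,2.0,0.82
cefathiamidine,0.28,0.49
cefathiamidine,1.0,1.29
cefathiamidine,2.0,1.63
flomoxef,0.28,1.07
flomoxef,1.0,8.30
flomoxef,2.0,11.54
cefmenoxime,0.28,0.00
cefmenoxime,1.0,0.71
cefmenoxime,2.0,1.14
cefpirome,0.28,0.21
cefpirome,1.0,0.86
cefpirome,2.0,1.67
cefminox,0.28,1.01
cefminox,1.0,8.26
cefminox,2.0,14.78
cefotiam,0.28,0.25
cefotiam,1.0,1.31
cefotiam,2.0,3.73
ceftazidime,0.28,0.00
ceftazidime,1.0,2.45
ceftazidime,2.0,5.47
cefodizime,0.28,0.51
cefodizime,1.0,0.94
cefodizime,2.0,3.47
cefoperazone,0.28,1.30
cefoperazone,1.0,5.75
cefoperazone,2.0,12.47
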