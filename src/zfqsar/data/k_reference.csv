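drug_id,k,discrepant
cefathiamidine,0.6439,0
cefradine,9.8110,0
cefotiam,2.0488,0
cefoperazone,6.5063,0
cefadroxil,6.4617,0
cefaclor,5.0027,0
ceftezole,5.2798,0
flomoxef,5.9111,0
cefminox,7.9122,0
cefoxitin,9.1638,0
cefodizime,1.7709,0
cefuroxime,2.3643,0
cefpirome,0.1689,1
ceftazidime,3.1702,0
cefotaxime,0.3023,0
ceftizoxime,7.1156,0
cefmenoxime,0.6493,0
cefalexin,9.3280,0
cefazolin,3.0851,0
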