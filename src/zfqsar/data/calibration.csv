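drug_id,slope_a,intercept_b,r,range_low,range_high,duplicate_flag
cefalexin,0.00175,0.00108,0.9962,1,500,1
cefradine,0.000156,0.000912,0.9918,1,500,0
cefadroxil,0.000107,0.000555,0.9967,1,500,0
cefaclor,0.000564,0.000483,0.9959,1,500,0
ceftizoxime,0.000732,0.000101,0.9969,1,500,0
ceftezole,0.000141,0.00122,0.9948,1,500,0
cefuroxime,0.0000936,0.00106,0.9950,1,500,0
cefoxitin,0.000205,0.000846,0.9899,1,500,0
cefazolin,0.000427,0.000186,0.9969,1,500,0
cefotaxime,0.00175,0.00108,0.9962,1,500,1
cefathiamidine,0.00562,0.00164,0.9969,1,500,0
flomoxef,0.0000711,0.000339,0.9953,1,500,0
cefmenoxime,0.000587,0.00268,0.9976,1,500,0
cefpirome,0.00509,0.00295,0.9969,1,500,0
cefminox,0.00146,0.0042,0.9960,1,500,0
cefotiam,0.0000419,0.000272,0.9935,1,500,0
ceftazidime,0.000259,0.000296,0.9981,1,500,0
cefodizime,0.000281,0.00268,0.9959,1,500,0
cefoperazone,0.000061,0.00102,0.9986,1,500,0
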