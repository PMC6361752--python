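drug_id,name,molecular_formula,table1_index,table3_index
cefalexin,Cefalexin,C16H17N3O4S,1,18
cefradine,Cefradine,C16H19N3O4S,2,2
cefadroxil,Cefadroxil,C16H17N3O5S,3,5
cefaclor,Cefaclor,C15H14ClN3O4S,4,6
ceftizoxime,Ceftizoxime,C13H13N5O5S2,5,16
cefuroxime,Cefuroxime,C16H16N4O8S,6,12
cefoxitin,Cefoxitin,C16H17N3O7S2,7,10
ceftezole,Ceftezole,C13H12N8O4S3,8,7
cefazolin,Cefazolin,C14H14N8O4S3,9,19
cefotaxime,Cefotaxime,C16H17N5O7S2,10,15
cefathiamidine,Cefathiamidine,C19H28N4O6S2,11,1
flomoxef,Flomoxef,C15H18F2N6O7S2,12,8
cefmenoxime,Cefmenoxime,C16H17N9O5S3,13,17
cefpirome,Cefpirome,C22H22N6O5S2,14,13
cefminox,Cefminox,C16H21N7O7S3,15,9
cefotiam,Cefotiam,C18H23N9O4S3,16,3
ceftazidime,Ceftazidime,C22H22N6O7S2,17,14
cefodizime,Cefodizime,C20H20N6O7S4,18,11
cefoperazone,Cefoperazone,C25H27N9O8S2,19,4
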