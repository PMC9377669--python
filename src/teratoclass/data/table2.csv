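compound_id,abbreviation,label,tier,cytotoxic,up,down
ampicillin,AMP,non_teratogen,1x,False,52,84
ampicillin,AMP,non_teratogen,20x,False,14,14
ascorbic_acid,ASC,non_teratogen,1x,False,47,58
ascorbic_acid,ASC,non_teratogen,20x,False,270,126
buspirone,BSP,non_teratogen,1x,False,39,5
buspirone,BSP,non_teratogen,20x,False,45,6
chlorpheniramine,CPA,non_teratogen,1x,False,44,5
chlorpheniramine,CPA,non_teratogen,20x,False,35,6
dextromethorphan,DEX,non_teratogen,1x,False,26,93
dextromethorphan,DEX,non_teratogen,20x,False,15,17
diphenhydramine,DPH,non_teratogen,1x,False,0,0
diphenhydramine,DPH,non_teratogen,20x,False,3,33
doxylamine,DOA,non_teratogen,1x,False,63,12
doxylamine,DOA,non_teratogen,20x,False,60,82
famotidine,FAM,non_teratogen,1x,False,25,1
famotidine,FAM,non_teratogen,20x,False,21,2
folic_acid,FOA,non_teratogen,1x,False,37,105
folic_acid,FOA,non_teratogen,20x,False,24,107
levothyroxine,LEV,non_teratogen,1x,False,77,131
levothyroxine,LEV,non_teratogen,20x,False,9,4
liothyronine,LIO,non_teratogen,1x,False,103,74
liothyronine,LIO,non_teratogen,20x,False,26,10
magnesium_chloride,MAG,non_teratogen,1x,False,90,137
magnesium_chloride,MAG,non_teratogen,20x,False,461,333
methicillin,MET,non_teratogen,1x,False,26,24
methicillin,MET,non_teratogen,20x,False,45,13
ranitidine,RAN,non_teratogen,1x,False,104,12
ranitidine,RAN,non_teratogen,20x,False,102,11
retinol,RET,non_teratogen,1x,False,0,0
retinol,RET,non_teratogen,20x,False,29,4
sucralose,SUC,non_teratogen,1x,False,153,38
sucralose,SUC,non_teratogen,20x,False,136,30
9-cis-retinoic_acid,9RA,teratogen,1x,False,434,297
9-cis-retinoic_acid,9RA,teratogen,20x,False,459,209
acitretin,ACI,teratogen,1x,False,570,138
acitretin,ACI,teratogen,20x,False,437,221
actinomycin_D,ACD,teratogen,1x,True,,
actinomycin_D,ACD,teratogen,20x,True,,
atorvastatin,ATO,teratogen,1x,False,123,5
atorvastatin,ATO,teratogen,20x,False,235,129
carbamazepine,CMZ,teratogen,1x,False,236,40
carbamazepine,CMZ,teratogen,10x,False,551,431
doxorubicin,DXR,teratogen,1x,True,,
doxorubicin,DXR,teratogen,20x,True,,
entinostat,ENT,teratogen,1x,False,579,156
entinostat,ENT,teratogen,20x,False,2916,1336
favipiravir,FPV,teratogen,1x,False,150,11
favipiravir,FPV,teratogen,20x,False,686,405
isotretinoin,ISO,teratogen,1x,False,1135,580
isotretinoin,ISO,teratogen,20x,False,1154,536
leflunomide,LFL,teratogen,1x,False,994,2332
lithium_chloride,LTH,teratogen,1x,False,395,64
lithium_chloride,LTH,teratogen,20x,False,1176,389
methotrexate,MTX,teratogen,1x,False,393,359
methotrexate,MTX,teratogen,20x,False,359,471
methylmercury,MEM,teratogen,1x,False,328,49
methylmercury,MEM,teratogen,20x,False,108,16
panobinostat,PAN,teratogen,1x,True,,
panobinostat,PAN,teratogen,20x,True,,
paroxetine,PAX,teratogen,1x,False,157,281
paroxetine,PAX,teratogen,20x,False,147,473
phenytoin,PHE,teratogen,1x,False,1,1
teriflunomide,TER,teratogen,1x,False,881,620
thalidomide,THD,teratogen,1x,False,304,238
thalidomide,THD,teratogen,20x,False,694,314
trichostatin_A,TSA,teratogen,1x,False,548,36
trichostatin_A,TSA,teratogen,20x,True,,
valproic_acid,VPA,teratogen,1x,False,882,407
valproic_acid,VPA,teratogen,1.67x,False,1827,731
vinblastine,VIN,teratogen,1x,True,,
vinblastine,VIN,teratogen,20x,True,,
vismodegib,VIS,teratogen,1x,False,14,18
vorinostat,VST,teratogen,1x,True,,
vorinostat,VST,teratogen,20x,True,,
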