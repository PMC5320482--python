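sample_id,commodity,analyte,conc_ugkg
CIT01,citrus,"2,4-D",2.6
CIT02,citrus,"2,4-D",8.5
CIT03,citrus,carbendazim,1.5
CIT04,citrus,carbendazim,5.5
CIT05,citrus,carbendazim,12.8
CIT06,citrus,thiabendazole,2.4
APP01,apple,carbendazim,3.5
APP02,apple,carbendazim,7.2
LYC01,lychee,carbendazim,3.1
TOM01,tomato,carbendazim,10.6
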