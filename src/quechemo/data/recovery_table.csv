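analyte,matrix,loq_ugkg,level_label,mean_recovery,rsd_intra,rsd_inter
"2,4-D",citrus,1.0,LOQ,91.9,1.8,4.4
"2,4-D",citrus,1.0,10xLOQ,96.5,1.9,3.1
"2,4-D",citrus,1.0,100xLOQ,98.6,3.6,7.6
"2,4-D",apple,1.0,LOQ,89.2,2.1,6.2
"2,4-D",apple,1.0,10xLOQ,92.1,2.3,1.9
"2,4-D",apple,1.0,100xLOQ,96.6,4.1,6.4
"2,4-D",mango,1.0,LOQ,89.4,11.7,2.9
"2,4-D",mango,1.0,10xLOQ,87.7,8.4,14.9
"2,4-D",mango,1.0,100xLOQ,93.5,5.1,8.5
"2,4-D",lychee,1.0,LOQ,70.6,4.3,5.9
"2,4-D",lychee,1.0,10xLOQ,79.2,4.2,2.5
"2,4-D",lychee,1.0,100xLOQ,76.5,5.1,7.6
"2,4-D",tomato,1.0,LOQ,71.3,4.5,8.7
"2,4-D",tomato,1.0,10xLOQ,78.1,5.2,1.2
"2,4-D",tomato,1.0,100xLOQ,72.2,3.7,9.4
"2,4-D",cucumber,1.0,LOQ,90.6,11.1,4.7
"2,4-D",cucumber,1.0,10xLOQ,94.9,5.6,12.7
"2,4-D",cucumber,1.0,100xLOQ,95.8,2.5,7.5
"2,4-D",green pepper,1.0,LOQ,73.5,4.4,6.8
"2,4-D",green pepper,1.0,10xLOQ,76.4,3.6,3.8
"2,4-D",green pepper,1.0,100xLOQ,76.1,6.7,10.3
"2,4-D",eggplant,1.0,LOQ,79.8,4.1,9.3
"2,4-D",eggplant,1.0,10xLOQ,78.9,2.5,5.0
"2,4-D",eggplant,1.0,100xLOQ,73.9,3.2,7.2
carbendazim,citrus,1.0,LOQ,86.9,1.2,10.1
carbendazim,citrus,1.0,10xLOQ,81.8,0.6,4.5
carbendazim,citrus,1.0,100xLOQ,74.9,4.8,7.1
carbendazim,apple,1.0,LOQ,105.5,1.5,5.5
carbendazim,apple,1.0,10xLOQ,100.5,1.3,6.0
carbendazim,apple,1.0,100xLOQ,104.7,1.5,2.2
carbendazim,mango,1.0,LOQ,84.9,2.8,6.7
carbendazim,mango,1.0,10xLOQ,83.7,1.4,10.4
carbendazim,mango,1.0,100xLOQ,82.9,1.1,10.6
carbendazim,lychee,1.0,LOQ,75.9,2.3,4.9
carbendazim,lychee,1.0,10xLOQ,84.0,3.8,7.4
carbendazim,lychee,1.0,100xLOQ,102.7,1.9,7.8
carbendazim,tomato,1.0,LOQ,79.6,1.6,5.3
carbendazim,tomato,1.0,10xLOQ,84.8,1.5,1.8
carbendazim,tomato,1.0,100xLOQ,86.3,1.1,6.3
carbendazim,cucumber,1.0,LOQ,85.6,1.3,8.2
carbendazim,cucumber,1.0,10xLOQ,88.9,1.0,10.2
carbendazim,cucumber,1.0,100xLOQ,84.4,1.4,7.7
carbendazim,green pepper,1.0,LOQ,83.8,1.1,1.5
carbendazim,green pepper,1.0,10xLOQ,89.4,2.1,1.0
carbendazim,green pepper,1.0,100xLOQ,85.6,2.8,11.6
carbendazim,eggplant,1.0,LOQ,101.7,8.9,3.6
carbendazim,eggplant,1.0,10xLOQ,107.0,6.5,4.3
carbendazim,eggplant,1.0,100xLOQ,96.8,2.4,3.8
thiabendazole,citrus,1.0,LOQ,107.4,4.5,5.9
thiabendazole,citrus,1.0,10xLOQ,104.6,0.9,3.5
thiabendazole,citrus,1.0,100xLOQ,86.1,10.9,4.1
thiabendazole,apple,1.0,LOQ,78.2,6.1,2.5
thiabendazole,apple,1.0,10xLOQ,87.8,4.4,3.7
thiabendazole,apple,1.0,100xLOQ,102.2,4.1,14.6
thiabendazole,mango,1.0,LOQ,96.3,11.9,8.7
thiabendazole,mango,1.0,10xLOQ,109.2,7.7,5.2
thiabendazole,mango,1.0,100xLOQ,106.4,5.8,9.9
thiabendazole,lychee,1.0,LOQ,102.8,6.6,13.9
thiabendazole,lychee,1.0,10xLOQ,107.5,4.4,5.2
thiabendazole,lychee,1.0,100xLOQ,108.2,10.2,8.4
thiabendazole,tomato,1.0,LOQ,81.8,9.8,5.8
thiabendazole,tomato,1.0,10xLOQ,92.3,6.0,12.8
thiabendazole,tomato,1.0,100xLOQ,96.4,9.4,10.2
thiabendazole,cucumber,1.0,LOQ,81.8,7.5,4.6
thiabendazole,cucumber,1.0,10xLOQ,99.8,4.5,2.9
thiabendazole,cucumber,1.0,100xLOQ,101.0,5.1,1.6
thiabendazole,green pepper,1.0,LOQ,97.3,7.7,13.8
thiabendazole,green pepper,1.0,10xLOQ,113.9,5.8,3.9
thiabendazole,green pepper,1.0,100xLOQ,108.7,10.8,10.2
thiabendazole,eggplant,1.0,LOQ,97.1,4.2,3.1
thiabendazole,eggplant,1.0,10xLOQ,107.7,3.8,5.9
thiabendazole,eggplant,1.0,100xLOQ,91.5,1.5,6.3
iprodione,citrus,1.5,LOQ,80.3,3.8,1.2
iprodione,citrus,1.5,10xLOQ,96.9,11.5,4.7
iprodione,citrus,1.5,100xLOQ,94.9,3.5,11.5
iprodione,apple,1.5,LOQ,89.7,5.9,1.5
iprodione,apple,1.5,10xLOQ,86.5,4.8,1.1
iprodione,apple,1.5,100xLOQ,92.4,3.2,6.2
iprodione,mango,1.5,LOQ,70.4,7.8,11.9
iprodione,mango,1.5,10xLOQ,80.6,4.3,12.6
iprodione,mango,1.5,100xLOQ,88.7,8.2,4.5
iprodione,lychee,1.5,LOQ,79.6,3.2,13.8
iprodione,lychee,1.5,10xLOQ,90.2,3.4,10.3
iprodione,lychee,1.5,100xLOQ,95.1,4.9,3.7
iprodione,tomato,1.5,LOQ,70.6,11.4,14.8
iprodione,tomato,1.5,10xLOQ,77.1,8.9,4.1
iprodione,tomato,1.5,100xLOQ,83.4,4.7,6.2
iprodione,cucumber,1.5,LOQ,92.2,3.9,9.5
iprodione,cucumber,1.5,10xLOQ,97.3,9.3,4.8
iprodione,cucumber,1.5,100xLOQ,109.8,4.8,8.3
iprodione,green pepper,1.5,LOQ,80.4,7.6,6.2
iprodione,green pepper,1.5,10xLOQ,87.6,8.7,3.5
iprodione,green pepper,1.5,100xLOQ,95.5,5.4,7.9
iprodione,eggplant,1.5,LOQ,71.0,11.3,16.9
iprodione,eggplant,1.5,10xLOQ,77.5,5.6,9.8
iprodione,eggplant,1.5,100xLOQ,82.2,5.8,9.0
prochloraz,citrus,1.0,LOQ,112.0,10.9,2.8
prochloraz,citrus,1.0,10xLOQ,82.3,5.4,1.3
prochloraz,citrus,1.0,100xLOQ,107.9,10.1,7.2
prochloraz,apple,1.0,LOQ,71.9,9.6,8.3
prochloraz,apple,1.0,10xLOQ,75.1,5.2,11.9
prochloraz,apple,1.0,100xLOQ,78.2,4.7,7.6
prochloraz,mango,1.0,LOQ,98.5,10.7,7.4
prochloraz,mango,1.0,10xLOQ,109.8,11.2,2.9
prochloraz,mango,1.0,100xLOQ,105.4,6.9,6.7
prochloraz,lychee,1.0,LOQ,86.7,1.8,3.3
prochloraz,lychee,1.0,10xLOQ,89.0,9.2,5.0
prochloraz,lychee,1.0,100xLOQ,85.6,7.5,4.2
prochloraz,tomato,1.0,LOQ,84.5,3.8,6.8
prochloraz,tomato,1.0,10xLOQ,88.3,1.8,9.5
prochloraz,tomato,1.0,100xLOQ,83.5,7.4,12.4
prochloraz,cucumber,1.0,LOQ,87.7,2.9,4.3
prochloraz,cucumber,1.0,10xLOQ,90.0,3.2,2.6
prochloraz,cucumber,1.0,100xLOQ,99.6,2.9,6.9
prochloraz,green pepper,1.0,LOQ,83.0,5.0,8.7
prochloraz,green pepper,1.0,10xLOQ,85.7,2.6,12.5
prochloraz,green pepper,1.0,100xLOQ,88.9,7.0,5.5
prochloraz,eggplant,1.0,LOQ,86.6,7.1,1.5
prochloraz,eggplant,1.0,10xLOQ,89.6,3.3,4.3
prochloraz,eggplant,1.0,100xLOQ,87.7,3.8,7.2
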