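analyte,matrix,dilution,slope,intercept,r_squared,me_printed
"2,4-D",methanol,ND,1991.1,325.61,0.9995,
"2,4-D",citrus,ND,3175.9,-158.4,0.9996,60
"2,4-D",citrus,D10,2562.4,56054,0.9988,29
"2,4-D",apple,ND,2190,5653.1,0.9984,10
"2,4-D",apple,D10,1923.4,-447.11,0.9989,-3
"2,4-D",mango,ND,2847.7,3979.9,0.9965,43
"2,4-D",mango,D10,2038.9,-1135.1,0.9957,17
"2,4-D",lychee,ND,1193.1,-1987.2,0.9995,-40
"2,4-D",lychee,D10,1551.9,10058,0.9985,-22
"2,4-D",tomato,ND,1592.8,8706.1,0.9988,-21
"2,4-D",tomato,D10,1510.7,261.61,0.9974,-24
"2,4-D",cucumber,ND,2449.5,18404.2,0.9974,23
"2,4-D",cucumber,D10,2035.4,-1566,0.9962,2
"2,4-D",green pepper,ND,1353.9,-1499.5,0.9991,-32
"2,4-D",green pepper,D10,1602.5,269.23,0.9982,-20
"2,4-D",eggplant,ND,1164,-1134.1,0.9995,-42
"2,4-D",eggplant,D10,1436,-390.65,0.9975,-28
carbendazim,methanol,ND,176731,99055,0.9998,
carbendazim,citrus,ND,268161.8,4949.8,0.9968,52
carbendazim,citrus,D10,223223,27773,0.9991,26
carbendazim,apple,ND,236215.6,2005.6,0.9992,34
carbendazim,apple,D10,190466,-15186,0.9956,8
carbendazim,mango,ND,229750.3,-453.5,0.9998,30
carbendazim,mango,D10,217618,200102,0.9985,23
carbendazim,lychee,ND,128246.2,9190.9,0.9979,-27
carbendazim,lychee,D10,136591,-2053.7,0.9965,-23
carbendazim,tomato,ND,215811.8,-5433.4,0.9994,22
carbendazim,tomato,D10,208961,-78290,0.9981,18
carbendazim,cucumber,ND,266631.1,4290,0.9989,51
carbendazim,cucumber,D10,218324,-79646,0.9974,24
carbendazim,green pepper,ND,226515.7,4113.7,0.9994,28
carbendazim,green pepper,D10,193792,-39174,0.9986,10
carbendazim,eggplant,ND,243354.1,1266.9,0.9959,38
carbendazim,eggplant,D10,194680,-105142,0.9987,10
thiabendazole,methanol,ND,122380,15957,0.9993,
thiabendazole,citrus,ND,196255.6,-953.8,0.9999,60
thiabendazole,citrus,D10,160230,16940,0.9990,31
thiabendazole,apple,ND,126499,1470.3,0.9992,3
thiabendazole,apple,D10,118125,20244,0.9979,-3
thiabendazole,mango,ND,104799.2,664.2,0.9988,-14
thiabendazole,mango,D10,100496,-9439.5,0.9976,-18
thiabendazole,lychee,ND,59966,-633.4,0.9996,-51
thiabendazole,lychee,D10,71458,-21003,0.9986,-42
thiabendazole,tomato,ND,142960.8,1786.3,0.9978,17
thiabendazole,tomato,D10,129274,-25846,0.9983,6
thiabendazole,cucumber,ND,134170.4,300.1,0.9993,10
thiabendazole,cucumber,D10,130301,-20946,0.9999,6
thiabendazole,green pepper,ND,89537.4,-654.9,0.9985,-27
thiabendazole,green pepper,D10,108280,-23063,0.9982,-12
thiabendazole,eggplant,ND,89113.6,-934.8,0.9942,-27
thiabendazole,eggplant,D10,110845,-7371.8,0.9994,-9
iprodione,methanol,ND,262.10,42.36,0.9994,
iprodione,citrus,ND,173.4,20.3,0.9981,-34
iprodione,citrus,D10,224.26,-206.81,0.9991,-14
iprodione,apple,ND,214.4,-159.8,0.9974,-18
iprodione,apple,D10,211.76,-142.7,0.9981,-19
iprodione,mango,ND,154.9,1665.4,0.9989,-41
iprodione,mango,D10,194.12,-286.19,0.9993,-26
iprodione,lychee,ND,119.8,-18.8,0.9997,-54
iprodione,lychee,D10,215.67,304.49,0.9994,-18
iprodione,tomato,ND,148.5,190.35,0.9975,-43
iprodione,tomato,D10,203.24,183.04,0.9989,-22
iprodione,cucumber,ND,335.4,73.08,0.9963,28
iprodione,cucumber,D10,305.57,151.04,0.9989,17
iprodione,green pepper,ND,217.3,222.6,0.9994,-17
iprodione,green pepper,D10,240.43,127.7,0.9998,-8
iprodione,eggplant,ND,121.05,-343.2,0.9987,-54
iprodione,eggplant,D10,141.56,148.84,0.9988,-46
prochloraz,methanol,ND,14490.3,7062.4,0.9995,
prochloraz,citrus,ND,18492.5,6884.3,0.9998,28
prochloraz,citrus,D10,16959.8,10809,0.9990,17
prochloraz,apple,ND,9118.8,-433.8,0.9995,-37
prochloraz,apple,D10,10237.7,-1370.6,0.9980,-29
prochloraz,mango,ND,19541.9,2436.5,0.9985,35
prochloraz,mango,D10,20050,-2753.5,0.9984,38
prochloraz,lychee,ND,7976.6,2117.7,0.994,-45
prochloraz,lychee,D10,11632,34578,0.9991,-20
prochloraz,tomato,ND,18652.4,22843.5,0.9982,29
prochloraz,tomato,D10,16274,-7563.4,0.9988,12
prochloraz,cucumber,ND,18557.7,2467.2,0.9990,28
prochloraz,cucumber,D10,18532,18399,0.9983,28
prochloraz,green pepper,ND,19996,-21135.3,0.9995,38
prochloraz,green pepper,D10,17957,2000.7,0.9998,24
prochloraz,eggplant,ND,8684.1,4553.8,0.9974,-40
prochloraz,eggplant,D10,12810,-1936,0.9996,-12
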