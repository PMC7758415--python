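accession,evolution_type,flavor_class,soluble_solids,fructose,glucose,citric_acid,malic_acid,sugar_acid_ratio
PL11,large-fruited,I,6.03,1290.00,838.50,251.33,144.17,5.38
PC4,cherry,I,8.17,1801.20,1023.15,451.92,266.03,3.93
PC2,cherry,I,7.23,2148.80,1220.60,267.21,157.29,7.94
RL2,large-fruited,I,4.77,1376.67,840.00,332.82,235.60,3.90
PC8,cherry,I,6.80,2391.07,1358.22,243.89,143.57,9.68
RL35,large-fruited,I,5.23,1465.17,894.00,178.67,126.48,7.73
RC6,cherry,I,7.13,1420.83,955.83,264.18,57.35,7.39
RC10,cherry,I,9.63,2145.00,1443.00,461.72,100.23,6.38
PL13,large-fruited,I,4.97,1120.00,728.00,278.40,159.70,4.22
PC7,cherry,I,7.07,1716.93,975.28,347.91,204.80,4.87
RL33,large-fruited,II,4.30,1307.83,798.00,255.74,181.04,4.82
RL19,large-fruited,II,4.27,1327.50,810.00,253.99,179.80,4.93
PL7,large-fruited,II,4.37,1100.00,715.00,344.13,197.40,3.35
PL9,large-fruited,II,6.10,1530.00,994.50,214.60,123.10,7.48
RC8,cherry,II,5.53,1475.83,992.83,359.38,78.02,5.64
PL4,large-fruited,II,4.43,1250.00,812.50,421.47,241.76,3.11
PC3,cherry,II,8.67,2096.13,1190.68,451.92,266.03,4.58
RC9,cherry,II,9.23,2374.17,1597.17,309.40,67.17,10.55
PC1,cherry,II,7.17,2085.60,1184.70,310.25,182.63,6.64
RL20,large-fruited,II,3.90,1140.67,696.00,268.01,189.72,4.01
RL12,large-fruited,II,6.30,1288.17,786.00,280.27,198.40,4.33
RL36,large-fruited,II,4.07,1278.33,780.00,253.99,179.80,4.74
PC6,cherry,II,11.43,2401.60,1364.20,243.89,143.57,9.72
RC1,cherry,II,5.20,1237.50,832.50,409.36,88.87,4.15
RL28,large-fruited,II,5.37,1602.83,978.00,544.77,385.64,2.77
RL26,large-fruited,II,5.53,1091.50,666.00,282.02,199.64,3.65
RC7,cherry,II,9.97,2090.00,1406.00,264.18,57.35,10.87
PL6,large-fruited,II,6.00,1200.00,780.00,278.40,159.70,4.52
RC5,cherry,II,6.80,1714.17,1153.17,390.32,84.73,6.04
RL8,large-fruited,II,4.67,1111.17,678.00,224.21,158.72,4.67
RL23,large-fruited,III,6.10,1091.50,666.00,210.20,148.80,4.90
RC4,cherry,III,7.03,1815.00,1221.00,514.08,111.60,4.85
RL25,large-fruited,III,6.97,1593.00,972.00,259.25,183.52,5.79
RL27,large-fruited,III,5.93,1396.33,852.00,120.87,85.56,10.89
RL37,large-fruited,III,6.40,1229.17,750.00,194.44,137.64,5.96
RL1,large-fruited,III,5.03,1337.33,816.00,201.44,142.60,6.26
PL2,large-fruited,III,5.47,1270.00,825.50,280.33,160.81,4.75
PL1,large-fruited,III,6.37,1560.00,1014.00,320.93,184.09,5.10
RL3,large-fruited,III,4.53,1337.33,816.00,283.77,200.88,4.44
RL9,large-fruited,III,5.63,1307.83,798.00,218.96,155.00,5.63
RC2,cherry,III,8.03,1925.00,1295.00,254.66,55.28,10.39
RL13,large-fruited,III,6.23,1317.67,804.00,252.24,178.56,4.92
RL31,large-fruited,III,6.80,1219.33,744.00,178.67,126.48,6.43
RL14,large-fruited,III,4.43,1071.83,654.00,197.94,140.12,5.11
PL12,large-fruited,III,6.33,1650.00,1072.50,286.13,164.13,6.05
PL3,large-fruited,III,5.67,1660.00,1079.00,274.53,157.48,6.34
PL15,large-fruited,III,5.67,1440.00,936.00,351.87,201.84,4.29
RL16,large-fruited,III,9.93,1760.17,1074.00,252.24,178.56,6.58
RL6,large-fruited,III,5.30,1032.50,630.00,234.72,166.16,4.15
RC11,cherry,III,6.73,1613.33,1085.33,490.28,106.43,4.52
RL21,large-fruited,III,5.73,1671.67,1020.00,436.17,308.76,3.61
PC5,cherry,III,6.67,2212.00,1256.50,245.69,144.63,8.89
RL10,large-fruited,III,3.67,1121.00,684.00,196.19,138.88,5.39
PL5,large-fruited,III,5.03,1220.00,793.00,288.07,165.24,4.44
PL14,large-fruited,III,3.83,1470.00,955.50,264.87,151.93,5.82
RC3,cherry,III,6.07,1585.83,1066.83,323.68,70.27,6.73
PL8,large-fruited,III,5.37,1050.00,682.50,255.20,146.39,4.31
RL24,large-fruited,III,6.10,1091.50,666.00,199.69,141.36,5.15
RL7,large-fruited,IV,4.27,1366.83,834.00,199.69,141.36,6.45
RL15,large-fruited,IV,6.07,1268.50,774.00,183.93,130.20,6.50
RL4,large-fruited,IV,5.53,1121.00,684.00,294.28,208.32,3.59
PL10,large-fruited,IV,6.67,1850.00,1202.50,187.53,107.57,10.34
RL17,large-fruited,IV,4.40,1081.67,660.00,215.46,152.52,4.73
RL22,large-fruited,IV,5.97,1347.17,822.00,271.51,192.20,4.68
RL32,large-fruited,IV,5.63,1396.33,852.00,301.29,213.28,4.37
RL5,large-fruited,IV,4.40,1130.83,690.00,143.64,101.68,7.42
RL29,large-fruited,IV,5.17,1248.83,762.00,196.19,138.88,6.00
RL11,large-fruited,IV,4.57,1268.50,774.00,203.19,143.84,5.89
RL30,large-fruited,IV,6.50,1150.50,702.00,206.70,146.32,5.25
RL18,large-fruited,IV,5.40,1022.67,624.00,264.50,187.24,3.65
RL34,large-fruited,IV,4.97,914.50,558.00,262.75,186.00,3.28
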