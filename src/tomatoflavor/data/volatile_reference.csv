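compound_id,name,functional_class,precursor_class,slope,intercept,r2,retention_time,reference_ri,descriptors,threshold,conc_min,conc_max,mean_conc,cv,printed_oav,olfactometry
V1,3-Methyl-1-butanol,alcohol,amino-acid,0.125,-0.00006,0.997,11.43,1210,malty;solvent-like,250,17.3,1328.78,108.26,0.34,<1,0
V2,1-Pentan-3-ol,alcohol,lipid,0.322,-0.342,0.995,12.16,1256,green,400,20.01,1036.58,109.26,0.34,<1,0
V3,1-Nonanol,alcohol,lipid,1.678,-0.032,0.994,9.21,1079,roses;oranges;grease-like,50000,20.62,556.15,142.28,2.24,<1,0
V4,1-Hexanol,alcohol,lipid,2.987,-0.0002,0.995,19.09,1650,resin;floral;green,500,208.8,24033.28,3109.08,1.47,6,0
V5,(Z)-3-Hexen-1-ol,alcohol,lipid,3.012,0.043,0.996,20.03,1695,lettuce-like,70,112.03,11848.2,977.52,0.85,14,1
V6,(E)-2-Hexen-1-ol,alcohol,lipid,0.192,0.049,0.99,14.91,1403,fruity,3900,24.74,1303.4,239.72,1.19,<1,0
V7,(2Z)-3-7-Dimethyl-2-6-octadien-1-ol,alcohol,carotenoid,0.386,-0.302,0.998,21.99,1807,rose-like,49000,41.7,395.92,84.32,1.50,<1,0
V8,2-4-Decadien-1-ol,alcohol,lipid,0.186,0.004,0.995,25.27,2042,fatty;deep-fried,2300,30.62,943.17,183.84,1.34,<1,0
V9,(E)-2-Octen-1-ol,alcohol,lipid,0.966,-0.330,0.999,18.66,1445,mushroom;earthy,4000,68.73,1297.18,235.40,0.95,<1,0
V10,6-Methyl-5-hepten-2-ol,alcohol,carotenoid,0.128,0.051,0.993,22.03,1810,floral,2000000,1.15,124.13,15.85,1.04,<1,0
V11,1-Octanol,alcohol,lipid,0.326,-0.467,0.996,17.8,1582,strong fatty citrus;rose-like,22000,18.67,251.23,65.94,1.14,<1,0
V12,2-Phenylethanol,alcohol,Phe,0.142,-0.009,0.996,31.74,2373,hyacinth;gardenia;nutty;fruity,140000,44.43,1227.32,255.21,1.56,<1,0
V13,3-7-Dimethyl-6-octen-1-ol,alcohol,carotenoid,0.023,0.008,0.991,26.64,2148,rose-like,46500,50.86,256.63,146.80,0.78,<1,0
V14,(2E-6E-10E)-3-7-11-15-Tetramethyl-2-6-10-14-hexadecatetraen-1-ol,alcohol,carotenoid,0.765,-0.232,0.991,24.46,1982,rose-like,50000,2.3,16.52,7.15,1.48,<1,0
V15,Hexanal,aldehyde,lipid,2.433,-0.561,0.997,11.48,1213,green;grassy,45,22.57,8523.65,1174.85,0.54,26,1
V16,(E)-2-Hexenal,aldehyde,lipid,1.39,0.004,0.992,14.96,1406,green apple-like;bitter,17,44.53,5041.44,619.87,0.72,36,1
V17,Nonanal,aldehyde,lipid,1.233,0.04,0.994,20.3,1711,citrus-like;soapy,28000,15.89,397.18,124.18,1.20,<1,0
V18,(E)-2-Octenal,aldehyde,lipid,2.18,0.043,0.997,21.4,1773,mushroom;earthy,30,45.11,3790.96,450.97,1.55,15,1
V19,Decanal,aldehyde,lipid,4.268,0.005,0.994,23.08,1887,fatty;citrus-like;floral,30,25.46,1343.38,165.74,0.69,6,0
V20,(E)-2-Nonenal,aldehyde,lipid,1.043,0.031,0.992,17.54,1570,fatty;green,190,15.89,397.18,124.18,1.15,1,0
V21,2-6-6-Trimethyl-1-cyclohexene-1-carboxaldehyde,aldehyde,carotenoid,0.026,-0.0008,0.991,22.11,1816,mint;fruity,5,26.95,461.14,110.06,1.05,22,1
V22,(Z)-3-7-Dimethyl-2-6-octadienal,aldehyde,carotenoid,1.897,0.006,0.994,20.28,1709,rose-like;citrus-like,30,26.7,1360.92,190.66,0.69,6,0
V23,(E)-3-7-Dimethyl-2-6-octadienal,aldehyde,carotenoid,4.548,0.072,0.992,21.11,1757,rose-like;citrus-like,1100,2.4,239.64,65.65,0.75,<1,0
V24,(E-E)-2-4-Decadienal,aldehyde,lipid,2.041,-0.033,0.99,29.28,2278,fatty;deep-fried,27,113.22,4679.54,1091.43,1.17,40,1
V25,(2E)-3-(3-Pentyl-2-oxiranyl)acrylaldehyde,aldehyde,lipid,0.038,-0.309,0.998,25.84,2086,metallic,38,30.17,3053.17,331.70,0.77,9,0
V26,(E)-2-Heptenal,aldehyde,lipid,2.042,-0.132,0.994,18.52,1622,green,13,20.92,1219.46,195.73,0.78,15,1
V27,5-9-13-Trimethyl-4-8-12-tetradecatrienal,aldehyde,carotenoid,0.712,0.034,0.997,30.15,2312,,,21.67,326,83.61,1.28,,0
V28,2-Undecenal,aldehyde,lipid,0.340,-0.231,0.994,20.48,1721,fatty;floral;citrus-like,44000,41.9,1422.62,256.16,1.07,<1,0
V29,(E-E)-2-4-Nonadienal,aldehyde,lipid,1.901,0.092,0.991,20.65,1731,fatty;green,62,39.15,676.24,200.43,0.86,3,0
V30,(2E-6E)-3-7-11-Trimethyl-2-6-10-dodecatrienal,aldehyde,carotenoid,0.977,-0.423,0.998,29.92,2303,soap-like;wax;violet;citrus-like,,29.53,437.26,87.28,0.84,,0
V31,(E)-2-Decenal,aldehyde,lipid,1.347,-0.036,0.996,19.53,1672,fatty,17000,18.5,888.61,235.18,0.80,<1,0
V32,1-Penten-3-one,ketone,lipid,2.096,0.003,0.992,9.77,1113,fruity;floral;green,940,17.14,221.37,71.28,0.89,<1,0
V33,3-Octanone,ketone,lipid,1.129,-0.332,0.995,12.44,1272,green;wax;vegetable-like,28000,22.52,216.36,51.17,0.66,<1,0
V34,1-Octen-3-one,ketone,lipid,2.062,-0.088,0.996,17.76,1579,mushroom-like,16,23.9,205.65,64.25,0.69,4,0
V35,6-10-Dimethyl-2-undecanone,ketone,carotenoid,0.488,0.055,0.993,20.13,1701,wax;fruity;fatty,7000,25.78,622.93,107.76,0.81,<1,0
V36,(E)-6-10-Dimethyl-5-9-undecadien-2-one,ketone,carotenoid,0.142,0.0005,0.994,23.16,1893,sweet;floral;ester-like,60,14.63,8821.9,1096.97,0.60,18,1
V37,4-(2-6-6-Trimethyl-1-cyclohexen-1-yl)-3-buten-2-one,ketone,carotenoid,0.449,-0.671,0.992,24.8,2005,floral;violet-like,3500,4.05,321.43,67.08,1.27,<1,0
V38,1-(2-6-6-Trimethyl-1-cyclohexen-1-yl)-2-buten-1-one,ketone,carotenoid,2.190,0.038,0.993,26.51,2138,baked apple;grape-like,13,211.46,647.49,429.47,1.13,33,1
V39,(E-Z)-6-10-Dimethyl-3-5-9-undecatrien-2-one,ketone,carotenoid,3.044,-0.490,0.995,26.42,2131,balsamic;violet-like,800,3.62,131.1,34.99,0.94,<1,0
V40,(E-E)-6-10-4-Trimethyl-5-9-13-pentadecatrien-2-one,ketone,carotenoid,0.099,-0.344,0.999,31.53,2365,fruity;floral,,10.47,4869.49,548.04,0.72,,0
V41,6-Methyl-5-hepten-2-one,ketone,carotenoid,1.432,-0.043,0.99,18.82,1637,fruity;floral,50,29.84,11923.39,1376.41,0.77,28,1
V42,6-10-14-Trimethyl-2-pentadecanone,ketone,carotenoid,1.376,-0.233,0.999,27.56,2210,sweet;tea-like,15000,1.99,42.93,8.80,1.15,<1,0
V43,2-Hydroxy-ethyl benzoate,ester,Phe,0.877,-0.00009,0.991,22.74,1862,herbs;sweet;spicy,900,45.1,6378.2,1225.83,1.34,1,0
V44,Ethyl tetradecanoate,ester,lipid,0.423,-0.491,0.994,26.25,2118,,4000000,24.29,193.35,62.62,1.01,<1,0
V45,Methyl hexadecanoate,ester,lipid,0.203,-0.509,0.992,28.92,2264,,2000000,16.02,693.12,188.92,1.11,<1,0
V46,Ethyl hexadecanoate,ester,lipid,1.047,0.007,0.992,29.45,2285,,2000000,41,2266.54,566.09,0.70,<1,0
V47,Dimethyl phthalate,ester,Phe,0.049,-0.132,0.997,30.63,2331,light fragrance,,22.97,305.44,63.94,0.82,,0
V48,Ethyl (9Z-12Z)-9-12-octadecadienoate,ester,lipid,0.183,-0.386,0.994,34.46,2488,,,22.23,191.42,61.25,0.77,,0
V49,Hept-4-yl isobutyl phthalate,ester,Phe,0.345,0.057,0.998,35.07,2516,light fragrance,,27.78,853.24,191.16,1.05,,0
V50,Ethyl octanoate,ester,lipid,0.122,-0.377,0.991,15.48,1439,pears litchi-like;sweet,13,28.94,180.99,71.64,0.65,6,0
V51,Methyl salicylate,ester,Phe,0.071,0.003,0.994,29.71,2295,wintergreen;herbal,40,23.77,1936.87,469.46,0.89,12,1
V52,Ethyl acetate,ester,lipid,4.823,-0.061,0.999,6.61,942,fruity,50000,24.75,1239.48,185.22,0.43,<1,0
V53,Isopropyl palmitate,ester,lipid,1.990,-0.223,0.99,29.74,2296,,,30.52,2662,264.65,1.08,,0
V54,2-4-Bis(1-1-dimethylethyl)-phenol,phenol,Phe,0.055,-0.367,0.995,30.39,2321,smoky;sweet,500000,31.89,497.59,101.47,1.53,<1,0
V55,4-Allyl-2-methoxyphenol,phenol,Phe,0.032,0.001,0.997,28.52,2249,lilac;cinnamon;cantaloupe-like,20,34.31,1752.73,330.04,2.51,17,1
V56,2-Methoxyphenol,phenol,Phe,0.422,-0.542,0.994,30.96,2344,smoky;sweet;woody;herbal,840,63.47,250.61,154.64,1.03,<1,0
V57,Alanylglycine,other,amino-acid,0.058,-0.399,0.998,3.84,487,chicken-like,,39.68,840.72,162.79,1.07,,0
V58,2-Pentyl-furan,other,lipid,1.099,0.383,0.99,14.93,1404,earthy;vegetable;malty;ham-like,6000,42.09,1157.35,301.08,0.60,<1,0
V59,2-Isobutylthiazole,other,amino-acid,1.049,0.097,0.996,20.74,1736,tomato vine;green,3.5,3.53,574.12,80.01,0.97,23,1
V60,3-(4-Methyl-3-pentenyl)-furan,other,carotenoid,0.328,-0.539,0.994,15.32,1429,minty,,21.95,201.22,63.22,0.73,,0
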