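# Published per-dose group means of the 13 neuromorphology features
# (six nocodazole doses, 36 multi-neuron images per dose; print-scale
# factors applied so values are in raw pixels/counts).
# anova_r2 = percent of total variance between dose groups.
feature,anova_r2,dose_0,dose_10,dose_50,dose_100,dose_200,dose_1000
somaCount,65.9,224,249,255,251,221,137
somaArea,62.3,56800,71600,86700,97000,94900,59100
neuriteLength,94.4,80800,59800,38500,25100,15600,8900
neuriteArea,95.3,203000,164000,119000,80000,49000,27000
attachmentPoint#,69.5,1260,1380,1400,1360,1150,640
endingPoint#,82.5,4400,3450,2700,2550,2160,1470
branchPoint#,91.0,49300,33600,20900,15200,10900,7500
Avg_somaArea,76.8,250,287,340,388,431,432
Avg_neuriteLength,88.0,372,244,151,100,71,65
Avg_neuriteArea,91.3,924,666,470,317,222,198
Avg_attachmentPoint#,58.4,5.62,5.54,5.46,5.42,5.20,4.68
Avg_endingPoint#,68.6,20.3,14.1,10.6,10.2,9.8,10.8
Avg_branchPoint#,85.1,22.7,13.7,8.2,6.0,5.0,5.5
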