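lineage,subtype,HS,D4,RAP,CCI
B,B naive,251,8,93,84
B,B intermediate,178,7,39,28
B,B memory,140,3,55,17
B,Plasmablast,73,97,198,179
CD4 T,CD4 T naive,1936,56,21,305
CD4 T,CD4 T proliferating,20,7,13,3
CD4 T,CD4 TEM,157,11,22,33
CD4 T,CD4 TCM,5683,676,1290,1042
CD4 T,CD4 CTL,11,0,3,7
CD4 T,Treg,149,16,24,36
CD8 T,CD8 T naive,401,6,20,118
CD8 T,CD8 T proliferating,10,0,11,8
CD8 T,CD8 TEM,926,80,146,453
CD8 T,CD8 TCM,153,4,14,24
other T,dnT,60,5,21,10
other T,gdT,117,10,12,7
other T,MAIT,64,1,12,21
NK,NK,1815,47,381,595
NK,NK Proliferating,60,5,18,52
NK,NK CD56bright,123,5,22,43
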