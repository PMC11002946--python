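# Tissue composition for partition-coefficient prediction (Rodgers-Rowland
# class equations).  Fractions per unit tissue volume: extracellular water
# (f_ew), intracellular water (f_iw), neutral lipids (f_nl), neutral
# phospholipids (f_np); acidic phospholipid concentration (ap, mg/g);
# tissue:plasma ratios of albumin (albumin_ratio, used for acids/weak bases)
# and lipoproteins (lipoprotein_ratio, used for neutrals); intracellular pH.
# Values are the standard published rat/human composition set used by
# tissue-composition Kp methods; "rest" is a soft-tissue average.
tissue,f_ew,f_iw,f_nl,f_np,ap_mg_per_g,albumin_ratio,lipoprotein_ratio,ph
adipose,0.135,0.017,0.853,0.0016,0.40,0.049,0.068,7.0
bone,0.100,0.346,0.017,0.0017,0.67,0.100,0.050,7.0
brain,0.162,0.620,0.039,0.0015,0.40,0.048,0.041,7.0
gut,0.282,0.475,0.038,0.0125,2.41,0.158,0.0324,7.0
heart,0.320,0.456,0.014,0.0111,2.25,0.157,0.0305,7.0
kidneys,0.273,0.483,0.012,0.0240,5.03,0.130,0.137,7.0
liver,0.161,0.573,0.014,0.0240,4.56,0.086,0.161,7.0
lungs,0.336,0.446,0.022,0.0128,3.91,0.212,0.168,7.0
muscle,0.118,0.630,0.010,0.0072,1.53,0.064,0.059,7.0
pancreas,0.120,0.664,0.041,0.0093,1.67,0.060,0.060,7.0
skin,0.382,0.291,0.060,0.0044,1.32,0.277,0.096,7.0
spleen,0.207,0.579,0.0077,0.0113,3.18,0.097,0.207,7.0
rest,0.200,0.550,0.020,0.0100,2.00,0.100,0.080,7.0
plasma,0.945,0.0,0.0023,0.0013,0.0,1.0,1.0,7.4
red_blood_cells,0.0,0.603,0.0017,0.0029,0.50,0.0,0.0,7.22
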