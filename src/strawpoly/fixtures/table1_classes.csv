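compound,class
1-O-Vanilloyl-β-D-glucose,hydroxybenzoic_acids
Vanillic acid,hydroxybenzoic_acids
Protocatechuic acid,hydroxybenzoic_acids
"2,5-Dihydrobenzoic acid",hydroxybenzoic_acids
Gentisic acid 2-O-β-glucoside,hydroxybenzoic_acids
Gentisic acid 5-O-β-glucoside,hydroxybenzoic_acids
Protocatechuic acid 4-β-glucoside,hydroxybenzoic_acids
4-Hydroxybenzoic acid,hydroxybenzoic_acids
"3,4-Dihydroxybenzaldehyde",hydroxybenzoic_acids
4-Hydroxybenzaldehyde,hydroxybenzoic_acids
Hydroxybenzoic-4-β-glucoside,hydroxybenzoic_acids
Neochlorogenic acid,hydroxycinnamic_acids
Chlorogenic acid,hydroxycinnamic_acids
4-Caffeoylquinic acid,hydroxycinnamic_acids
cis-5-O-p-Coumaroylquinic acid,hydroxycinnamic_acids
5-O-Feruloylquinic acid,hydroxycinnamic_acids
trans-3-Feruloylquinic acid,hydroxycinnamic_acids
Feruloylquinic acid isomer,hydroxycinnamic_acids
Caffeic acid,hydroxycinnamic_acids
Ferulic acid,hydroxycinnamic_acids
p-Coumaric acid,hydroxycinnamic_acids
Caffeoylquinic acid,hydroxycinnamic_acids
"4,5-Dicaffeoylquinic acid",hydroxycinnamic_acids
Caffeoylshikimic acid,hydroxycinnamic_acids
Apigenin-8-C-glucoside,flavones
Isovitexin 2″-O-arabinoside,flavones
Isoschaftoside,flavones
Neoschaftoside,flavones
Apigenin-6-C-glucosyl-8-C-arabinoside,flavones
Luteolin-6-C-glucoside,flavones
Luteolin-8-C-glucoside,flavones
Apigenin 7-O-neohesperidoside,flavones
Luteolin,flavones
6-Methoxyluteolin 7-rhamnoside,flavones
Diosmetin,flavones
Tricin-O-neohesperoside isomer,flavones
Tricin-7-O-glucoside,flavones
Tricin-7-O-rhamnosyl-glucuronide,flavones
Tricin-4-(O-erythro) ether glucoside,flavones
Tricin,flavones
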