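EICOSANOID_BIOSYNTHESIS	suppressive|mouse|lung|synthetic illustrative entry	Ptgs1	Ptgs2	Ptges	Ptges2	Ptges3	Alox5	Alox15	Ptgis	Tbxas1	Hpgd
WNT_BETA_CATENIN	suppressive|mouse|pan-cancer|synthetic illustrative entry	Ctnnb1	Wnt1	Wnt3a	Wnt5a	Fzd1	Lrp5	Lrp6	Axin1	Apc	Tcf7	Lef1
TYPE_I_IFN_RESPONSE	activating|mouse|pan-cancer|synthetic illustrative entry	Ifnb1	Irf3	Irf7	Sting1	Cgas	Ifnar1	Ifnar2	Stat1	Stat2	Isg15
ANTIGEN_PRESENTATION	activating|mouse|pan-cancer|synthetic illustrative entry	Tap1	Tap2	Tapbp	B2m	H2-K1	H2-D1	Psmb8	Psmb9	Erap1
PGE2_SIGNALING	suppressive|mouse|lung|synthetic illustrative entry	Ptger1	Ptger2	Ptger3	Ptger4	Creb1	Camp	Vipr1
CHEMOKINE_T_CELL_RECRUITMENT	activating|mouse|pan-cancer|synthetic illustrative entry	Cxcl9	Cxcl10	Cxcl11	Ccl4	Ccl5	Cxcr3	Ccr5
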