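ff_name,ccd_code,cg_name,category
CHL1,CLR,CHL1,lipid
POPC,POV,POPC,lipid
POPE,6OU,POPE,lipid
POPG,PGW,POPG,lipid
POPS,D39,POPS,lipid
DPPC,PCF,DPPC,lipid
CYSP,CYP,CYSP,ptm
BDDM,LMT,,detergent
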