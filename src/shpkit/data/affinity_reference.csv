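# Equilibrium dissociation constants (uM) for individual SH2 domains of
# SHP1/SHP2 binding singly phosphorylated ITIM or ITSM of PD-1 and BTLA.
# source=printed : measured value.
# source=ordinal : no numeric value available; placeholder chosen only to
#   respect the established qualitative preference of each SH2 domain
#   (nSH2 prefers BTLA-ITIM, cSH2 prefers BTLA-ITSM). Do not use these
#   rows for quantitative statements; categorical mode-ranking conclusions
#   are invariant to their exact values as long as the orderings hold.
receptor,motif,phosphatase,sh2,kd_uM,source
PD-1,ITIM,SHP1,nSH2,0.27,printed
PD-1,ITSM,SHP1,nSH2,0.083,printed
PD-1,ITIM,SHP1,cSH2,ND,printed
PD-1,ITSM,SHP1,cSH2,1.7,printed
PD-1,ITIM,SHP2,nSH2,0.38,printed
PD-1,ITSM,SHP2,nSH2,0.14,printed
PD-1,ITIM,SHP2,cSH2,1.4,printed
PD-1,ITSM,SHP2,cSH2,0.10,printed
BTLA,ITIM,SHP1,nSH2,0.064,printed
BTLA,ITSM,SHP1,cSH2,0.86,printed
BTLA,ITSM,SHP1,nSH2,0.5,ordinal
BTLA,ITIM,SHP1,cSH2,2.0,ordinal
BTLA,ITIM,SHP2,nSH2,0.15,ordinal
BTLA,ITSM,SHP2,nSH2,0.45,ordinal
BTLA,ITSM,SHP2,cSH2,0.25,ordinal
BTLA,ITIM,SHP2,cSH2,1.2,ordinal
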