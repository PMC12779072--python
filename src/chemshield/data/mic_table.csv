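# Broth-microdilution MIC values (ug/mL) of compounds 2a-2f on the 2-fold
# ladder 78/156/312/625/1250 against nine strains; NT = not tested.
organism,class,2a,2b,2c,2d,2e,2f
B. cereus,gram+,625,625,625,625,1250,625
B. subtilis,gram+,625,625,625,312,625,312
Y. pseudotuberculosis,gram-,625,625,625,625,625,625
K. pneumoniae,gram-,625,625,625,312,1250,156
E. coli,gram-,625,625,625,625,1250,625
P. aeruginosa,gram-,625,625,625,625,625,625
S. aureus,gram+,625,312,625,625,1250,312
E. faecalis,gram+,625,625,625,625,625,625
C. albicans,fungal,156,312,156,78,1250,78
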