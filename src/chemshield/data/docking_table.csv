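# Rigid-receptor docking results for compounds 2d and 2f against four
# antibacterial targets; ki_printed_* restate the report's own Ki column for
# consistency checking against the exp(dG/RT) conversion.
ligand,receptor_pdb,binding_energy_kcal_mol,ki_printed_value,ki_printed_unit,n_hbonds,hbond_residues,vdw_residues
2d,1HNJ,-8.91,296.19,nM,3,Thr80;Ala83;Ala86;Asp107;Val108;Leu142;Ile156;Phe157;Asn193;Leu205;Met207;Gly209;Asn210;Val212;Phe213;Asn247;Ile250;Asn274;Phe304,Thr81;Ala109;Ala111;Cys112;Leu189;Thr190;Leu191;Ala246;Gly305;Gly306
2d,2VF5,-10.90,10.19,nM,4,Trp313;Ser316;Ile429;Asp432;Arg472;Gln475;His566;Val567;Glu569;Ala572;Tyr576,Tyr312;Leu317;Gly473;Asp474;Ala520;Asp548;Val570
2d,5CDN,-7.51,3.12,uM,6,Ala94;Gln95;Asp96;Phe97;Tyr101;Val104;Asp105;Phe110;Thr129;Phe480;Asp482,Pro102;Gly106;Gly111;Lys130;Ile131;Arg479;Gly481;Asp483
2d,5MMN,-9.08,221.83,nM,4,Ala47;Glu50;Gly77;Ile78;Pro79;Val97;Leu98;Val118;Gly119;Thr165,Glu42;Asp45;Asn46;Asp73;Ile94;Val120;Ser121
2f,1HNJ,-7.92,1.55,uM,4,Trp32;Thr37;Ile156;Leu189;Thr190;Leu205;Met207;Gly209;Asn210;Phe213;His244;Asn274;Ser276;Gly306,Arg36;Thr81;Ala111;Cys112;Leu142;Phe157;Leu191;Asn193;Val212;Ala246;Ile250;Phe304;Gly305
2f,2VF5,-9.26,162.93,nM,2,Tyr312;Trp313;Ser316;Leu317;His435;Gly473;Gln475;Pro521;Asn522;Leu525;His566;Val567;Glu568;Val570,Asp432;Arg472;Asp474;Ala520;Asp548;Glu569
2f,5CDN,-8.21,964.45,nM,3,Ala94;Gln95;Val104;Gly108;Asn109;Thr129;Phe110;Arg479;Phe480;Asp482;Asp483,Tyr101;Pro102;Asp105;Gly106;Ile131;Gly481
2f,5MMN,-8.22,945.54,nM,3,Asn46;Ala47;Ile48;Glu50;Gly75;Arg76;Gly77;Pro79;Val97;Leu98;Val118;Gly119;Ser121;Thr165,Asp45;Asp46;Asp73;Ile78;Ile94;Val120
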