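# Bis-piperazine Schiff-base candidates 2a-2f; densities were not published,
# so the density column is left empty (use infer_density with a LAC anchor).
id,formula,density_g_cm3
2a,C30H44N6O2,
2b,C31H46N6O2,
2c,C32H48N6O2,
2d,C33H50N6O2,
2e,C34H52N6O2,
2f,C35H54N6O2,
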