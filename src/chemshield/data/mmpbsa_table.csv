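# End-point MM/PBSA free-energy components (kcal/mol) for the 2VF5-2d complex,
# averaged over 1000 snapshots from the last 20 ns of a 100 ns MD trajectory.
complex,term,value_kcal_mol,sd
2VF5-2d,vdw,-42.73,0.61
2VF5-2d,ele,-22.59,3.87
2VF5-2d,polar,41.99,0.95
2VF5-2d,nonpolar,-3.98,0.04
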