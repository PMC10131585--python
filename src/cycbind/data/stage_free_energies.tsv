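stage	system	action	term	free_energy	uncertainty	time_ns
1	Ligand	Apply conform. restraint	dG_apply_RMSD	11.97	2.96	389
2	Ligand	Apply orient. restraints	dG_apply_ThetaPhiPsi	6.61	0.00	0
3	Complex	Binding of restrained ligand	-kT ln(S* I C0)	-12.92	0.79	6956
4	Complex	Release phi direct. restraint	dG_release_phi	-0.49	0.11	17
5	Complex	Release theta direct. restraint	dG_release_theta	-0.05	0.01	20
6	Complex	Release Psi orient. restraint	dG_release_Psi	-0.20	0.02	19
7	Complex	Release Phi orient. restraint	dG_release_Phi	-0.29	0.17	17
8	Complex	Release Theta orient. restraint	dG_release_Theta	-0.23	0.02	19
9	Complex	Release conform. restraint	dG_release_RMSD	-11.03	1.59	91
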