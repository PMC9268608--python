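protein	ligand	interaction_type	residues
CSF1R	trans_minus	pi_pi	Trp550
CSF1R	trans_minus	hydrogen_bond	Tyr546;Arg549;Trp550
CSF1R	trans_plus	pi_pi	Phe797
CSF1R	trans_plus	hydrogen_bond	Thr663;Cys666;Asp796
CSF1R	cis_minus	pi_pi	Trp550
CSF1R	cis_minus	hydrogen_bond	Arg549;Trp550;Thr663
CSF1R	cis_plus	pi_pi	Tyr665
CSF1R	cis_plus	hydrogen_bond	Thr663;Tyr665;Asp796
CSF1R	pexidartinib	pi_pi	Trp550
CSF1R	pexidartinib	hydrogen_bond	Arg459;Trp550;Glu664;Cys666
EGFR	trans_minus	hydrogen_bond	Lys745;Asp855;Phe856
EGFR	trans_plus	hydrogen_bond	Lys745;Asp855;Phe856
EGFR	cis_minus	hydrogen_bond	Lys745;Phe856
EGFR	cis_plus	hydrogen_bond	Lys745;Asp855;Phe856
EGFR	erlotinib	hydrogen_bond	Asp855;Phe856
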