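# Molecular band table for head-and-neck tissue Raman spectra.
# center (cm^-1)	tolerance (cm^-1)	region	assignment
center	tolerance	region	assignment
1003	15	fingerprint	phenylalanine ring breathing (protein)
1032	15	fingerprint	phenylalanine C-H in-plane bending (protein)
1084	15	fingerprint	phosphate stretching (lipid / nucleic acid)
1260	15	fingerprint	amide III in-plane deformation (lipid / protein)
1266	15	fingerprint	amide III / =C-H in-plane (lipid / protein)
1335	15	fingerprint	guanine deformation (DNA / RNA)
1448	15	fingerprint	CH2 bending / scissoring (lipid, protein)
1656	15	fingerprint	amide I alpha-helix / C=C stretch (protein, unsaturated lipid)
1730	15	fingerprint	C=O stretch (ester, phospholipid)
2865	15	high_wavenumber	CH2 stretching (esterified lipid, fatty acid)
2920	15	high_wavenumber	CH3 stretching (protein)
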