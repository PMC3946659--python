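"""Chemistry tables: ring atoms, hydrogen-bond donors/acceptors, cations."""

#: tryptophan indole, six-membered (benzene) ring
TRP_SIX_RING = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")
#: tryptophan indole, five-membered (pyrrole) ring
TRP_FIVE_RING = ("CG", "CD1", "NE1", "CE2", "CD2")
#: all nine indole ring atoms
TRP_RING_ATOMS = tuple(dict.fromkeys(TRP_SIX_RING + TRP_FIVE_RING))

#: other aromatic sidechain rings (for stacking against non-Trp partners)
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: sidechain hydrogen-bond donor heavy atoms per residue type
SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
}

#: sidechain hydrogen-bond acceptor heavy atoms per residue type
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

#: cationic groups: residue -> atoms whose mean position is the charge center
CATION_GROUPS = {
    "LYS": ("NZ",),
    "ARG": ("CZ", "NH1", "NH2", "NE"),
}
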