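"""Amino-acid chemistry tables: hydrogen-bond donors/acceptors and charges.

Heavy-atom-only criteria are used for static structures (deposited models
rarely carry hydrogens), so donor/acceptor status is attached to the heavy
atom bearing the proton.  His, Ser, Thr and Tyr are listed as both donor and
acceptor; backbone N is always a donor (except proline) and backbone O
always an acceptor.
"""

from __future__ import annotations

# side-chain heavy atoms able to donate a hydrogen bond
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}

# side-chain heavy atoms able to accept a hydrogen bond
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
}

# charged-group heavy atoms for salt-bridge detection
CHARGED_POSITIVE: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
CHARGED_NEGATIVE: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

BACKBONE_DONOR = "N"
BACKBONE_ACCEPTOR = "O"
# C-terminal carboxylate oxygen, an acceptor when present
TERMINAL_ACCEPTOR = "OXT"


def donor_atoms(residue_name: str, atom_names: set[str]) -> list[str]:
    """Heavy-atom donor names present in a residue."""
    rn = residue_name.upper()
    out = []
    if BACKBONE_DONOR in atom_names and rn != "PRO":
        out.append(BACKBONE_DONOR)
    for name in SIDECHAIN_DONORS.get(rn, ()):
        if name in atom_names:
            out.append(name)
    return out


def acceptor_atoms(residue_name: str, atom_names: set[str]) -> list[str]:
    """Heavy-atom acceptor names present in a residue."""
    rn = residue_name.upper()
    out = []
    if BACKBONE_ACCEPTOR in atom_names:
        out.append(BACKBONE_ACCEPTOR)
    if TERMINAL_ACCEPTOR in atom_names:
        out.append(TERMINAL_ACCEPTOR)
    for name in SIDECHAIN_ACCEPTORS.get(rn, ()):
        if name in atom_names:
            out.append(name)
    return out


def is_ionic_pair(res_a: str, atoms_a: list[str], res_b: str, atoms_b: list[str]) -> bool:
    """True if the two residues can form a salt bridge (Asp/Glu vs Arg/Lys/His)."""
    a_pos = res_a.upper() in CHARGED_POSITIVE
    a_neg = res_a.upper() in CHARGED_NEGATIVE
    b_pos = res_b.upper() in CHARGED_POSITIVE
    b_neg = res_b.upper() in CHARGED_NEGATIVE
    return (a_pos and b_neg) or (a_neg and b_pos)


# ---------------------------------------------------------------------------
# Side-chain heavy-atom templates for the synthetic builder.  Offsets are in
# Angstrom relative to CA, oriented roughly along +x ("outward" before the
# builder rotates them); geometry is idealised, not physical.

SIDECHAIN_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", (1.5, 0.0, 0.0))],
    "VAL": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG1", "C", (2.3, 1.1, 0.0)),
        ("CG2", "C", (2.3, -1.1, 0.0)),
    ],
    "LEU": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.6, 0.9, 0.0)),
        ("CD1", "C", (3.9, 0.3, 0.0)),
        ("CD2", "C", (2.7, 2.0, 1.0)),
    ],
    "ILE": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG1", "C", (2.6, 0.9, 0.0)),
        ("CG2", "C", (1.8, -1.0, 1.0)),
        ("CD1", "C", (3.9, 0.3, 0.0)),
    ],
    "MET": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.6, 0.9, 0.0)),
        ("SD", "S", (4.0, 0.4, 0.0)),
        ("CE", "C", (5.0, 1.6, 0.0)),
    ],
    "SER": [("CB", "C", (1.5, 0.0, 0.0)), ("OG", "O", (2.4, 1.1, 0.0))],
    "THR": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("OG1", "O", (2.4, 1.1, 0.0)),
        ("CG2", "C", (2.2, -1.2, 0.3)),
    ],
    "CYS": [("CB", "C", (1.5, 0.0, 0.0)), ("SG", "S", (2.8, 1.1, 0.0))],
    "ASP": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.7, 0.8, 0.0)),
        ("OD1", "O", (3.8, 0.2, 0.0)),
        ("OD2", "O", (2.7, 2.1, 0.0)),
    ],
    "ASN": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.7, 0.8, 0.0)),
        ("OD1", "O", (3.8, 0.2, 0.0)),
        ("ND2", "N", (2.7, 2.1, 0.0)),
    ],
    "GLU": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.6, 0.9, 0.0)),
        ("CD", "C", (3.9, 0.4, 0.0)),
        ("OE1", "O", (5.0, 1.0, 0.0)),
        ("OE2", "O", (4.0, -0.9, 0.0)),
    ],
    "GLN": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.6, 0.9, 0.0)),
        ("CD", "C", (3.9, 0.4, 0.0)),
        ("OE1", "O", (5.0, 1.0, 0.0)),
        ("NE2", "N", (4.0, -0.9, 0.0)),
    ],
    "LYS": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.6, 0.9, 0.0)),
        ("CD", "C", (3.9, 0.4, 0.0)),
        ("CE", "C", (5.0, 1.2, 0.0)),
        ("NZ", "N", (6.3, 0.7, 0.0)),
    ],
    "ARG": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.6, 0.9, 0.0)),
        ("CD", "C", (3.9, 0.4, 0.0)),
        ("NE", "N", (5.0, 1.2, 0.0)),
        ("CZ", "C", (6.3, 0.9, 0.0)),
        ("NH1", "N", (7.3, 1.7, 0.0)),
        ("NH2", "N", (6.6, -0.4, 0.0)),
    ],
    "HIS": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.7, 0.8, 0.0)),
        ("ND1", "N", (3.9, 0.2, 0.0)),
        ("CD2", "C", (2.9, 2.1, 0.0)),
        ("CE1", "C", (5.0, 1.0, 0.0)),
        ("NE2", "N", (4.3, 2.3, 0.0)),
    ],
    "PHE": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.7, 0.8, 0.0)),
        ("CD1", "C", (3.9, 0.2, 0.0)),
        ("CD2", "C", (2.9, 2.1, 0.0)),
        ("CE1", "C", (5.1, 0.9, 0.0)),
        ("CE2", "C", (4.1, 2.8, 0.0)),
        ("CZ", "C", (5.2, 2.2, 0.0)),
    ],
    "TYR": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.7, 0.8, 0.0)),
        ("CD1", "C", (3.9, 0.2, 0.0)),
        ("CD2", "C", (2.9, 2.1, 0.0)),
        ("CE1", "C", (5.1, 0.9, 0.0)),
        ("CE2", "C", (4.1, 2.8, 0.0)),
        ("CZ", "C", (5.2, 2.2, 0.0)),
        ("OH", "O", (6.4, 2.9, 0.0)),
    ],
    "TRP": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.7, 0.8, 0.0)),
        ("CD1", "C", (3.9, 0.2, 0.0)),
        ("CD2", "C", (2.9, 2.1, 0.0)),
        ("NE1", "N", (5.0, 1.1, 0.0)),
        ("CE2", "C", (4.3, 2.4, 0.0)),
        ("CE3", "C", (2.3, 3.3, 0.0)),
        ("CZ2", "C", (5.0, 3.6, 0.0)),
        ("CZ3", "C", (3.0, 4.5, 0.0)),
        ("CH2", "C", (4.3, 4.7, 0.0)),
    ],
    "PRO": [
        ("CB", "C", (1.5, 0.0, 0.0)),
        ("CG", "C", (2.2, 1.2, 0.5)),
        ("CD", "C", (1.3, 2.2, 1.0)),
    ],
}
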