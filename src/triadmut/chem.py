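"""Fixed chemical typing tables for the 20 standard amino acids.

All rules in this package operate on heavy atoms only (cleaned structures
carry no hydrogens), so donor/acceptor roles and hydrophobicity are assigned
from standard residue topology rather than computed protonation states.

Table version: "v1" (recorded inside persisted signature parameters so a
database built with one table is never silently queried with another).
"""

from __future__ import annotations

CHEM_TABLE_VERSION = "v1"

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Fixed order of main-chain atoms in every 24-atom triad correspondence.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

# --- side-chain hydrogen-bond donors / acceptors (heavy atoms) --------------

SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}

SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

#: Bonded heavy-atom antecedents of each donor, used to measure the donor
#: angle on hydrogen-free structures (angle antecedent–donor–acceptor).
DONOR_ANTECEDENTS = {
    ("*", "N"): ("CA",),  # backbone amide
    ("ARG", "NE"): ("CD", "CZ"),
    ("ARG", "NH1"): ("CZ",),
    ("ARG", "NH2"): ("CZ",),
    ("ASN", "ND2"): ("CG",),
    ("GLN", "NE2"): ("CD",),
    ("HIS", "ND1"): ("CG", "CE1"),
    ("HIS", "NE2"): ("CD2", "CE1"),
    ("LYS", "NZ"): ("CE",),
    ("SER", "OG"): ("CB",),
    ("THR", "OG1"): ("CB",),
    ("TRP", "NE1"): ("CD1", "CE2"),
    ("TYR", "OH"): ("CZ",),
}

# --- formal charge groups (evaluation-side ionic contacts) ------------------

POSITIVE_CHARGE_ATOMS = {
    "ARG": {"NE", "NH1", "NH2", "CZ"},
    "LYS": {"NZ"},
    "HIS": {"CG", "CD2", "CE1", "ND1", "NE2"},
}

NEGATIVE_CHARGE_ATOMS = {
    "ASP": {"CG", "OD1", "OD2"},
    "GLU": {"CD", "OE1", "OE2"},
}

# --- aromatic rings ---------------------------------------------------------

AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    # TRP indole treated as one nine-atom ring system with one centroid
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

# --- hydrophobic (apolar) atoms ---------------------------------------------
# Carbons whose bonded heavy neighbours are only carbon (plus the thioether
# sulfur of MET).  Derived once from standard side-chain topology.

APOLAR_ATOMS = {
    "ALA": {"CB"},
    "ARG": {"CB", "CG"},
    "ASN": {"CB"},
    "ASP": {"CB"},
    "GLN": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "HIS": {"CB"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "LYS": {"CB", "CG", "CD"},
    "MET": {"CB", "SD"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG"},
    "THR": {"CG2"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "VAL": {"CB", "CG1", "CG2"},
}

#: Carbons carrying no hydrogen (cannot act as weak C–H donors):
#: backbone carbonyl C plus quaternary/carboxyl/amide/guanidinium carbons.
NO_H_CARBONS = {
    ("*", "C"),
    ("ARG", "CZ"),
    ("ASN", "CG"), ("ASP", "CG"),
    ("GLN", "CD"), ("GLU", "CD"),
    ("HIS", "CG"),
    ("PHE", "CG"), ("TYR", "CG"), ("TYR", "CZ"),
    ("TRP", "CG"), ("TRP", "CD2"), ("TRP", "CE2"),
}

# --- category labels for proposed residue pairs -----------------------------

POSITIVE_RESIDUES = frozenset({"ARG", "LYS", "HIS"})
NEGATIVE_RESIDUES = frozenset({"ASP", "GLU"})
AROMATIC_RESIDUES = frozenset({"TRP", "TYR", "HIS", "PHE"})
HYDROPHOBIC_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "PRO"})

# --- pharmacophore classes for aCSM-style signatures ------------------------

PHARMACOPHORE_CLASSES = (
    "hydrophobic", "aromatic", "positive", "negative",
    "donor", "acceptor", "sulfur", "neutral",
)

_SULFUR_ATOMS = {("CYS", "SG"), ("MET", "SD")}


def pharmacophore_classes(res_name: str, atom_name: str) -> frozenset:
    """Classes of one heavy atom.  Multi-class membership is allowed; an atom
    matching nothing else is 'neutral' so every atom contributes to the
    signature."""
    classes = set()
    if atom_name in APOLAR_ATOMS.get(res_name, ()):
        classes.add("hydrophobic")
    if atom_name in AROMATIC_RINGS.get(res_name, ()):
        classes.add("aromatic")
    if atom_name in POSITIVE_CHARGE_ATOMS.get(res_name, ()):
        classes.add("positive")
    if atom_name in NEGATIVE_CHARGE_ATOMS.get(res_name, ()):
        classes.add("negative")
    if atom_name == "N" or atom_name in SIDECHAIN_DONORS.get(res_name, ()):
        classes.add("donor")
    if atom_name == "O" or atom_name in SIDECHAIN_ACCEPTORS.get(res_name, ()):
        classes.add("acceptor")
    if (res_name, atom_name) in _SULFUR_ATOMS:
        classes.add("sulfur")
    if not classes:
        classes.add("neutral")
    return frozenset(classes)


def element_of(atom_name: str) -> str:
    """Infer the element symbol from a standard PDB heavy-atom name."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"
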