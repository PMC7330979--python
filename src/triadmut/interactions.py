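"""Side-chain interaction detection and inter-residue contact classification.

Two distinct rule sets live here:

* the *database-side* detector (:func:`detect_sidechain_interactions`), a
  verbatim implementation of the fixed atom lists and cutoffs used to seed
  triad-pair templates (hydrogen bond < 3.50 Å, ionic < 6.00 Å, disulfide
  < 2.08 Å, side-chain atoms only);
* the *evaluation-side* classifier (:func:`classify_contacts`), which counts
  the seven contact types (hydrogen bond, weak HB, ionic, aromatic, polar,
  weak polar, hydrophobic) used to compare wild and mutant structures.

The atom lists of the database-side table are implemented exactly as printed
even where chemically surprising (LYS NZ can hydrogen-bond but is not in the
ionic list; HIS lists ring carbons under ionic): changing them would silently
change database contents.

Since cleaned structures carry no hydrogens, angle criteria are measured at
the donor using its bonded heavy-atom antecedent(s); this is an approximation
to hydrogen-explicit geometry and is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .structure import Structure

# ---------------------------------------------------------------------------
# database-side rules (fixed table)
# ---------------------------------------------------------------------------

INTERACTION_KINDS = ("hydrogen_bond", "ionic", "disulfide")

#: distance cutoffs, Å (strict upper bounds)
INTERACTION_CUTOFFS = {
    "hydrogen_bond": 3.50,
    "ionic": 6.00,
    "disulfide": 2.08,
}

#: side-chain atoms that may donate/accept a hydrogen bond
HB_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2", "OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"NE2", "OE1"},
    "LYS": {"NZ"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}

#: ionic pairing requires one atom from each charge group
IONIC_POSITIVE = {"ARG": {"CZ"}, "HIS": {"CD2", "CE1", "CG"}}
IONIC_NEGATIVE = {"ASP": {"CG", "OD1", "OD2"}, "GLU": {"CD"}}

DISULFIDE_ATOMS = {"CYS": {"SG"}}

#: residue types able to seed a non-disulfide template (first-residue groups)
POLAR_GROUP_RESIDUES = (
    "ARG", "ASN", "ASP", "GLN", "GLU", "HIS", "LYS", "SER", "THR", "TRP", "TYR",
)


@dataclass(frozen=True)
class Interaction:
    """One detected side-chain contact between two residues.

    ``res_a`` is always the lower residue key, and each unordered atom pair is
    reported exactly once.
    """
    kind: str
    res_a: tuple
    res_b: tuple
    res_name_a: str
    res_name_b: str
    atom_a: str
    atom_b: str
    distance: float


def _sequence_adjacent(key_a, key_b) -> bool:
    return key_a[0] == key_b[0] and abs(key_a[1] - key_b[1]) <= 1


def _pair_interactions(res_a, res_b, cutoffs):
    """All database-side interactions between two residues (a < b by key)."""
    out = []
    if res_a.key > res_b.key:
        res_a, res_b = res_b, res_a
    if res_a.key == res_b.key or _sequence_adjacent(res_a.key, res_b.key):
        return out

    def dist(x, y):
        return float(np.linalg.norm(x.coords - y.coords))

    def atoms_of(res, table):
        names = table.get(res.res_name, ())
        return [res.atoms[n] for n in names if n in res.atoms]

    def emit(kind, aa, ab, swap=False):
        d = dist(aa, ab)
        if d < cutoffs[kind]:
            out.append(Interaction(
                kind=kind, res_a=res_a.key, res_b=res_b.key,
                res_name_a=res_a.res_name, res_name_b=res_b.res_name,
                atom_a=ab.name if swap else aa.name,
                atom_b=aa.name if swap else ab.name,
                distance=round(d, 4)))

    for aa in atoms_of(res_a, HB_ATOMS):
        for ab in atoms_of(res_b, HB_ATOMS):
            emit("hydrogen_bond", aa, ab)
    for aa in atoms_of(res_a, IONIC_POSITIVE):
        for ab in atoms_of(res_b, IONIC_NEGATIVE):
            emit("ionic", aa, ab)
    for aa in atoms_of(res_a, IONIC_NEGATIVE):
        for ab in atoms_of(res_b, IONIC_POSITIVE):
            emit("ionic", ab, aa, swap=True)
    for aa in atoms_of(res_a, DISULFIDE_ATOMS):
        for ab in atoms_of(res_b, DISULFIDE_ATOMS):
            emit("disulfide", aa, ab)
    return out


def detect_sidechain_interactions(s: Structure, cutoffs: dict | None = None):
    """Detect all Table-style side-chain interactions in a cleaned structure.

    Intra-residue and sequence-adjacent (|Δseq| ≤ 1, same chain) pairs are
    excluded; each unordered pair is reported once, lower residue key first.
    """
    cutoffs = dict(INTERACTION_CUTOFFS, **(cutoffs or {}))
    eligible = [r for r in s
                if r.res_name in HB_ATOMS or r.res_name in IONIC_POSITIVE
                or r.res_name in IONIC_NEGATIVE or r.res_name in DISULFIDE_ATOMS]
    out = []
    for i, ra in enumerate(eligible):
        for rb in eligible[i + 1:]:
            out.extend(_pair_interactions(ra, rb, cutoffs))
    out.sort(key=lambda x: (x.res_a, x.res_b, x.kind, x.atom_a, x.atom_b))
    return out


def pair_interacts(res_a, res_b, cutoffs: dict | None = None) -> bool:
    """True if the two residues already form any database-side interaction."""
    cutoffs = dict(INTERACTION_CUTOFFS, **(cutoffs or {}))
    return bool(_pair_interactions(res_a, res_b, cutoffs))


# ---------------------------------------------------------------------------
# evaluation-side classifier (seven contact types)
# ---------------------------------------------------------------------------

CONTACT_TYPES = (
    "hydrogen_bond", "weak_hb", "ionic", "aromatic",
    "polar", "weak_polar", "hydrophobic",
)

#: distance cutoffs for the evaluation-side rules, Å
CONTACT_CUTOFFS = {
    "polar": 3.5,          # donor–acceptor, no angle
    "weak_polar": 3.6,     # C–H donor to acceptor, no angle
    "ionic": 4.0,
    "aromatic_atom": 4.5,
    "aromatic_centroid": 6.0,
    "hydrophobic": 4.5,
}

HB_MIN_ANGLE = 90.0          # antecedent–donor–acceptor, degrees
WEAK_HB_ANGLE_RANGE = (30.0, 150.0)


@dataclass
class ContactProfile:
    """Counts of the seven inter-residue contact types."""
    counts: dict = field(default_factory=lambda: {t: 0 for t in CONTACT_TYPES})

    def __getitem__(self, t):
        return self.counts[t]

    def as_dict(self):
        return dict(self.counts)


def contact_delta(wild: ContactProfile, mutant: ContactProfile) -> dict:
    """Per-type signed count difference mutant − wild."""
    return {t: mutant[t] - wild[t] for t in CONTACT_TYPES}


def _angle_deg(a, b, c) -> float:
    """Angle at b, degrees."""
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


class _AtomTable:
    """Flat typed-atom arrays over one structure."""

    def __init__(self, s: Structure):
        self.residues = list(s)
        self.res_idx, self.names, self.coords = [], [], []
        for i, r in enumerate(self.residues):
            for a in r.atoms.values():
                self.res_idx.append(i)
                self.names.append(a.name)
                self.coords.append(a.coords)
        self.coords = np.asarray(self.coords).reshape(-1, 3)
        self.res_idx = np.asarray(self.res_idx)

    def eligible(self, i, j) -> bool:
        """Different residues, not sequence-adjacent in the same chain."""
        ri, rj = self.residues[self.res_idx[i]], self.residues[self.res_idx[j]]
        if ri.key == rj.key:
            return False
        return not _sequence_adjacent(ri.key, rj.key)

    def select(self, predicate):
        return [k for k in range(len(self.names))
                if predicate(self.residues[self.res_idx[k]], self.names[k])]


def _donor_angle_ok(res, donor_name, donor_xyz, acc_xyz, lo, hi) -> bool:
    ante_names = (chem.DONOR_ANTECEDENTS.get((res.res_name, donor_name))
                  or chem.DONOR_ANTECEDENTS.get(("*", donor_name)) or ())
    antecedents = [res.atoms[n].coords for n in ante_names if n in res.atoms]
    if not antecedents:
        return True  # no antecedent present: angle criterion passes
    return any(lo <= _angle_deg(a, donor_xyz, acc_xyz) <= hi for a in antecedents)


def classify_contacts(s: Structure) -> ContactProfile:
    """Count the seven evaluation contact types in a cleaned structure.

    Unordered atom (or ring) pairs are counted once; an atom pair may
    contribute to several types.  Pairs within one residue or between
    sequence-adjacent residues of the same chain never count.
    """
    tab = _AtomTable(s)
    prof = ContactProfile()

    def is_donor(res, name):
        return (name == "N" and res.res_name != "PRO") or \
            name in chem.SIDECHAIN_DONORS.get(res.res_name, ())

    def is_acceptor(res, name):
        return name == "O" or name in chem.SIDECHAIN_ACCEPTORS.get(res.res_name, ())

    def is_weak_donor(res, name):
        if chem.element_of(name) != "C":
            return False
        return (res.res_name, name) not in chem.NO_H_CARBONS and ("*", name) not in chem.NO_H_CARBONS

    donors = set(tab.select(is_donor))
    acceptors = set(tab.select(is_acceptor))
    weak_donors = set(tab.select(is_weak_donor))

    def donor_acceptor_pairs(donor_ids, max_d):
        """Unordered pairs where one end donates and the other accepts."""
        seen = set()
        for i in donor_ids:
            tree_ids = np.where(
                np.linalg.norm(tab.coords - tab.coords[i], axis=1) <= max_d)[0]
            for j in tree_ids:
                if j == i or j not in acceptors or not tab.eligible(i, j):
                    continue
                key = (min(i, j), max(i, j))
                if key in seen:
                    continue
                seen.add(key)
                yield i, j

    # polar / hydrogen bond
    for i, j in donor_acceptor_pairs(donors, CONTACT_CUTOFFS["polar"]):
        prof.counts["polar"] += 1
        ri = tab.residues[tab.res_idx[i]]
        rj = tab.residues[tab.res_idx[j]]
        hb = _donor_angle_ok(ri, tab.names[i], tab.coords[i], tab.coords[j],
                             HB_MIN_ANGLE, 180.0)
        # the partner may itself be a donor (e.g. hydroxyls): either
        # orientation satisfying the angle makes it a hydrogen bond
        if not hb and j in donors and i in acceptors:
            hb = _donor_angle_ok(rj, tab.names[j], tab.coords[j], tab.coords[i],
                                 HB_MIN_ANGLE, 180.0)
        if hb:
            prof.counts["hydrogen_bond"] += 1

    # weak polar / weak hydrogen bond (C–H donors)
    lo, hi = WEAK_HB_ANGLE_RANGE
    for i, j in donor_acceptor_pairs(weak_donors, CONTACT_CUTOFFS["weak_polar"]):
        prof.counts["weak_polar"] += 1
        ri = tab.residues[tab.res_idx[i]]
        # antecedent of a carbon donor: any bonded heavy atom is acceptable;
        # approximate with the residue CA (side-chain carbons) or N (for CA)
        name = tab.names[i]
        ante = ri.atoms.get("N" if name == "CA" else "CA")
        if ante is None:
            ok = True
        else:
            ok = lo <= _angle_deg(ante.coords, tab.coords[i], tab.coords[j]) <= hi
        if ok:
            prof.counts["weak_hb"] += 1

    # ionic: opposing formal-charge groups
    pos = tab.select(lambda r, n: n in chem.POSITIVE_CHARGE_ATOMS.get(r.res_name, ()))
    neg = set(tab.select(lambda r, n: n in chem.NEGATIVE_CHARGE_ATOMS.get(r.res_name, ())))
    for i in pos:
        d = np.linalg.norm(tab.coords - tab.coords[i], axis=1)
        for j in np.where(d <= CONTACT_CUTOFFS["ionic"])[0]:
            if j in neg and tab.eligible(i, j):
                prof.counts["ionic"] += 1

    # aromatic: ring-ring, atom distance <= 4.5 or centroid distance <= 6.0
    rings = []
    for r in s:
        names = chem.AROMATIC_RINGS.get(r.res_name)
        if not names:
            continue
        xyz = np.array([r.atoms[n].coords for n in names if n in r.atoms])
        if len(xyz) >= 3:
            rings.append((r, xyz, xyz.mean(axis=0)))
    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            ra, xa, ca = rings[a]
            rb, xb, cb = rings[b]
            if _sequence_adjacent(ra.key, rb.key):
                continue
            if np.linalg.norm(ca - cb) <= CONTACT_CUTOFFS["aromatic_centroid"]:
                prof.counts["aromatic"] += 1
                continue
            dmin = np.min(np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2))
            if dmin <= CONTACT_CUTOFFS["aromatic_atom"]:
                prof.counts["aromatic"] += 1

    # hydrophobic: apolar atom pairs (KD-tree; largest atom set)
    apolar = tab.select(lambda r, n: n in chem.APOLAR_ATOMS.get(r.res_name, ()))
    if apolar:
        sub = tab.coords[apolar]
        tree = cKDTree(sub)
        for ii, jj in tree.query_pairs(CONTACT_CUTOFFS["hydrophobic"]):
            i, j = apolar[ii], apolar[jj]
            if tab.eligible(i, j):
                prof.counts["hydrophobic"] += 1

    return prof
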