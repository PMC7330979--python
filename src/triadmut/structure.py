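"""Uniform coordinate model and PDB input/output.

Structures are read through gemmi and cleaned into a minimal in-memory model:
heavy atoms only, one location per atom (highest occupancy wins, ties broken
by file order), heteroatoms and waters removed, author numbering preserved.
Only the first model of multi-model (e.g. NMR) files is used.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .chem import BACKBONE_ATOMS, STANDARD_AA, element_of
from .errors import EmptyStructureError, MissingChainError, StructureError

logger = logging.getLogger(__name__)

#: (chain_id, author seq number, insertion code) — the residue identity used
#: everywhere; proposals cite these author labels.
ResidueKey = tuple


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: dict = field(default_factory=dict)  # name -> Atom, insertion order

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.seq_number}{self.insertion_code}".strip()

    def get(self, name: str):
        return self.atoms.get(name)

    @property
    def has_full_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    @property
    def ca(self):
        return self.atoms.get("CA")

    def sidechain_atoms(self):
        """Atoms beyond the main chain (CB and outward)."""
        return [a for n, a in self.atoms.items() if n not in BACKBONE_ATOMS]

    def add_atom(self, atom: Atom):
        if atom.name in self.atoms:
            raise StructureError(f"duplicate atom {atom.name} in residue {self.label}")
        self.atoms[atom.name] = atom


@dataclass
class Structure:
    id: str
    residues: list = field(default_factory=list)  # file order, grouped by chain

    def __post_init__(self):
        self._index = {r.key: r for r in self.residues}

    def __len__(self):
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def get_residue(self, key: ResidueKey):
        return self._index.get(tuple(key))

    def add_residue(self, res: Residue):
        if res.key in self._index:
            raise StructureError(f"duplicate residue key {res.key}")
        self.residues.append(res)
        self._index[res.key] = res

    def chains(self) -> dict:
        out: dict = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)


def _resolve_altlocs(locations):
    """Pick one location per atom name: highest occupancy, tie -> first seen."""
    best = {}
    for atom in locations:
        cur = best.get(atom.name)
        if cur is None or atom.occupancy > cur.occupancy + 1e-12:
            best[atom.name] = atom
    return best


def read_structure(path, chain: str | None = None, drop_het: bool = True) -> Structure:
    """Read and clean a PDB-format file.

    Parameters
    ----------
    path : str or Path
        PDB-format coordinate file.
    chain : str, optional
        Keep only this chain; raise :class:`MissingChainError` if absent.
    drop_het : bool
        Remove HETATM records and waters (default).  Hydrogens and
        non-standard residues are always removed.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]  # first model only

    available = [ch.name for ch in model]
    if chain is not None and chain not in available:
        raise MissingChainError(f"chain {chain!r} not in {path} (has {available})")

    out = Structure(id=st.name.strip() or path.stem)
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.is_water():
                continue
            if drop_het and res.het_flag == "H":
                continue
            if res.name not in STANDARD_AA:
                logger.warning("%s: dropping non-standard residue %s %s%s",
                               path.name, res.name, ch.name, res.seqid.num)
                continue
            cand = []
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                cand.append(Atom(
                    name=atom.name,
                    element=atom.element.name or element_of(atom.name),
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    altloc="",
                ))
            picked = _resolve_altlocs(cand)
            if not picked:
                continue
            icode = res.seqid.icode.strip()
            r = Residue(chain_id=ch.name, seq_number=res.seqid.num,
                        insertion_code=icode, res_name=res.name, atoms=picked)
            if out.get_residue(r.key) is not None:
                logger.warning("%s: duplicate residue %s skipped", path.name, r.key)
                continue
            out.add_residue(r)
    if len(out) == 0:
        raise EmptyStructureError(f"{path}: no residues left after cleaning")
    return out


def write_structure(s: Structure, path) -> None:
    """Write a Structure as a fixed-width PDB file (via gemmi)."""
    if len(s) == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chains: dict = {}
    for res in s:
        ch = chains.get(res.chain_id)
        if ch is None:
            ch = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = ch
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
        gres.het_flag = "A"
        for atom in res.atoms.values():
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coords)
            ga.occ = atom.occupancy
            ga.b_iso = 0.0
            gres.add_atom(ga)
        ch.add_residue(gres)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise StructureError(f"cannot write PDB file {path}: {exc}") from exc
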