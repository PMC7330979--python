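"""Shared test utilities: structure builders, PDB record formatting, and the
independent oracles (quaternion superposition, union-find single linkage)."""

from __future__ import annotations

import numpy as np

from triadmut.structure import Atom, Residue, Structure
from triadmut.triads import SidechainAtom, TriadPair


def make_structure(residue_specs, structure_id="test"):
    """Build a Structure from (chain, seq, res_name, {atom_name: xyz}) tuples."""
    s = Structure(id=structure_id)
    for chain, seq, name, atoms in residue_specs:
        res = Residue(chain_id=chain, seq_number=seq, insertion_code="", res_name=name)
        for atom_name, xyz in atoms.items():
            res.add_atom(Atom(name=atom_name, element=atom_name[0], coords=np.asarray(xyz, float)))
        s.add_residue(res)
    return s


def atom_record(serial, name, resname, chain, seq, xyz, occ=1.0, altloc=" ",
                icode=" ", element=None, het=False):
    """One fixed-width PDB ATOM/HETATM line."""
    element = element or name[0]
    name_field = name if len(name) == 4 else f" {name:<3s}"
    tag = "HETATM" if het else "ATOM  "
    x, y, z = xyz
    return (f"{tag}{serial:5d} {name_field}{altloc}{resname:>3s} {chain}{seq:4d}{icode}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}")


def write_pdb_text(path, lines):
    path.write_text("\n".join(lines + ["END"]) + "\n")


def horn_rmsd(moving, fixed):
    """Independent quaternion (Horn) superposition RMSD oracle."""
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    n = len(moving)
    x = moving - moving.mean(axis=0)
    y = fixed - fixed.mean(axis=0)
    sxx = x.T @ y
    a = np.array([
        [sxx[0, 0] + sxx[1, 1] + sxx[2, 2], sxx[1, 2] - sxx[2, 1],
         sxx[2, 0] - sxx[0, 2], sxx[0, 1] - sxx[1, 0]],
        [sxx[1, 2] - sxx[2, 1], sxx[0, 0] - sxx[1, 1] - sxx[2, 2],
         sxx[0, 1] + sxx[1, 0], sxx[2, 0] + sxx[0, 2]],
        [sxx[2, 0] - sxx[0, 2], sxx[0, 1] + sxx[1, 0],
         -sxx[0, 0] + sxx[1, 1] - sxx[2, 2], sxx[1, 2] + sxx[2, 1]],
        [sxx[0, 1] - sxx[1, 0], sxx[2, 0] + sxx[0, 2],
         sxx[1, 2] + sxx[2, 1], -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]],
    ])
    lam = np.linalg.eigvalsh(a).max()
    msd = max(0.0, ((x ** 2).sum() + (y ** 2).sum() - 2.0 * lam) / n)
    return float(np.sqrt(msd))


def union_find_clusters(dist, cutoff):
    """Brute-force single linkage: connected components of the <=cutoff graph."""
    n = dist.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= cutoff:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def random_triad(rng, source="rnd", with_sidechains=True, base=None, noise=0.0):
    """A synthetic but valid TriadPair with random (or perturbed) coordinates."""
    if base is None:
        bb = rng.normal(0.0, 4.0, size=(24, 3))
    else:
        bb = base + rng.normal(0.0, 1.0, size=(24, 3)) * noise
    side = ()
    if with_sidechains:
        side = (
            SidechainAtom(0, "CB", "C", tuple(bb[5] + rng.normal(0, 1, 3))),
            SidechainAtom(0, "OG", "O", tuple(bb[5] + rng.normal(0, 1, 3))),
            SidechainAtom(1, "CB", "C", tuple(bb[17] + rng.normal(0, 1, 3))),
            SidechainAtom(1, "OG1", "O", tuple(bb[17] + rng.normal(0, 1, 3))),
        )
    return TriadPair(
        source_id=f"{source}:A",
        keys=tuple(("A", i, "") for i in (1, 2, 3, 11, 12, 13)),
        res_names=("ALA", "SER", "ALA", "ALA", "THR", "ALA"),
        backbone_coords=bb,
        sidechain_atoms=side,
    )
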