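"""Triad-pair extraction, single-linkage clustering, and the template database.

A *triad pair* is the storage and alignment unit: two interacting residues
n and n' plus their sequence flanks (n-1, n+1, n'-1, n'+1).  Its 24
main-chain coordinates follow the fixed order
(n-1, n, n+1, n'-1, n', n'+1) x (N, CA, C, O); side-chain atoms of n and n'
(CB and outward) are kept for grafting.

Templates are grouped two ways, mirroring the original database layout:

* 122 storage *categories*: ordered (first residue x partner) pairs over the
  11 polar residue types able to hydrogen-bond or form ionic contacts
  (11 x 11 = 121), plus one disulfide category (CYS-CYS).  "First" means the
  lower author residue number within the source structure.
* 12 *groups* keyed by the first residue type (the 11 polar types plus CYS);
  the CYS group holds only CYS-CYS disulfide triads.

Within each category, triads are clustered by single linkage under the
main-chain triad RMSD (both pairings tried, side chains excluded so that one
representative generalizes across side-chain conformers); the first member of
each cluster under a deterministic ordering is its representative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .chem import BACKBONE_ATOMS, element_of
from .errors import DatabaseError, IncompleteTriadError, TriadmutError
from .interactions import (POLAR_GROUP_RESIDUES, Interaction,
                           detect_sidechain_interactions)
from .structure import Atom, Residue, Structure, read_structure, write_structure
from .superpose import triad_rmsd

logger = logging.getLogger(__name__)

DISULFIDE_CATEGORY = "CYS-CYS"


def enumerate_categories():
    """The 122 storage categories: 11 x 11 ordered polar pairs + disulfide."""
    cats = [f"{a}-{b}" for a in POLAR_GROUP_RESIDUES for b in POLAR_GROUP_RESIDUES]
    cats.append(DISULFIDE_CATEGORY)
    return cats


def enumerate_groups():
    """The 12 first-residue groups (11 polar types + CYS)."""
    return list(POLAR_GROUP_RESIDUES) + ["CYS"]


@dataclass(frozen=True)
class SidechainAtom:
    site: int          # 0 -> residue n, 1 -> residue n'
    name: str
    element: str
    coords: tuple      # xyz, Å


@dataclass(frozen=True, eq=False)
class TriadPair:
    """Two triads around an (actual or candidate) interacting residue pair."""
    source_id: str                 # structure label + chain, e.g. "1ABC:A"
    keys: tuple                    # 6 residue keys, order (n-1,n,n+1,n'-1,n',n'+1)
    res_names: tuple               # 6 three-letter codes, same order
    backbone_coords: np.ndarray    # (24, 3)
    sidechain_atoms: tuple = ()    # SidechainAtom of n and n'
    interaction: Interaction | None = None
    cluster_size: int = 1

    def __post_init__(self):
        bb = np.asarray(self.backbone_coords, dtype=float)
        if bb.shape != (24, 3) or not np.all(np.isfinite(bb)):
            raise IncompleteTriadError(
                f"triad pair needs exactly 24 finite main-chain coordinates, got {bb.shape}")
        object.__setattr__(self, "backbone_coords", bb)
        if len(self.keys) != 6 or len(self.res_names) != 6:
            raise IncompleteTriadError("triad pair needs 6 residues")
        if len(set(self.keys)) != 6:
            raise IncompleteTriadError("the two triads must not share residues")

    @property
    def pair(self):
        return (self.keys[1], self.keys[4])

    @property
    def pair_names(self):
        return (self.res_names[1], self.res_names[4])

    @property
    def kind(self):
        return self.interaction.kind if self.interaction else None

    @property
    def category(self) -> str:
        if self.kind == "disulfide":
            return DISULFIDE_CATEGORY
        return f"{self.res_names[1]}-{self.res_names[4]}"

    @property
    def group(self) -> str:
        return "CYS" if self.kind == "disulfide" else self.res_names[1]

    @property
    def rep_id(self) -> str:
        def fmt(k):
            return f"{k[0]}{k[1]}{k[2]}"
        kind = self.kind or "target"
        return f"{self.source_id}|{fmt(self.keys[1])}-{fmt(self.keys[4])}|{kind}" + (
            f"|{self.interaction.atom_a}-{self.interaction.atom_b}" if self.interaction else "")

    def sidechain_coords(self, site: int) -> np.ndarray:
        xyz = [a.coords for a in self.sidechain_atoms if a.site == site]
        return np.asarray(xyz, dtype=float).reshape(-1, 3)

    def all_atoms(self):
        """(res_name, atom_name, xyz) over the 24 main-chain atoms plus the
        stored side chains — the atom set a signature is computed on."""
        out = []
        for i in range(6):
            for j, name in enumerate(BACKBONE_ATOMS):
                out.append((self.res_names[i], name, self.backbone_coords[4 * i + j]))
        site_res = {0: self.res_names[1], 1: self.res_names[4]}
        for a in self.sidechain_atoms:
            out.append((site_res[a.site], a.name, np.asarray(a.coords)))
        return out


def _triad_residues(chain_residues, pos):
    """(prev, this, next) by chain position; None if a flank is missing or a
    flank is not a +-1 step in author numbering."""
    if pos <= 0 or pos >= len(chain_residues) - 1:
        return None
    prev, this, nxt = chain_residues[pos - 1], chain_residues[pos], chain_residues[pos + 1]
    if this.seq_number - prev.seq_number > 1 or nxt.seq_number - this.seq_number > 1:
        return None
    return prev, this, nxt


def build_triad_pair(s: Structure, chain_residues, pos_n: int, pos_np: int,
                     interaction: Interaction | None = None) -> TriadPair:
    """Assemble a TriadPair around chain positions ``pos_n`` < ``pos_np``.

    Raises :class:`IncompleteTriadError` if a flank is missing, a backbone
    atom is absent, or the triads overlap.
    """
    if pos_np - pos_n < 3:
        raise IncompleteTriadError("triads would share residues (separation < 3)")
    tri_a = _triad_residues(chain_residues, pos_n)
    tri_b = _triad_residues(chain_residues, pos_np)
    if tri_a is None or tri_b is None:
        raise IncompleteTriadError("missing sequence flank")
    six = list(tri_a) + list(tri_b)
    coords = []
    for r in six:
        if not r.has_full_backbone:
            raise IncompleteTriadError(f"residue {r.label} lacks a full backbone")
        coords.extend(r.atoms[a].coords for a in BACKBONE_ATOMS)
    sidechains = []
    for site, r in ((0, tri_a[1]), (1, tri_b[1])):
        for a in r.sidechain_atoms():
            sidechains.append(SidechainAtom(site=site, name=a.name,
                                            element=a.element, coords=tuple(a.coords)))
    chain_id = six[0].chain_id
    return TriadPair(
        source_id=f"{s.id}:{chain_id}",
        keys=tuple(r.key for r in six),
        res_names=tuple(r.res_name for r in six),
        backbone_coords=np.asarray(coords),
        sidechain_atoms=tuple(sidechains),
        interaction=interaction,
    )


def extract_triad_pairs(s: Structure, inters) -> list:
    """One TriadPair per interaction whose six residues all exist with full
    backbones; failing interactions are skipped with a logged reason."""
    out = []
    chains = s.chains()
    pos_of = {}
    for ch, residues in chains.items():
        for i, r in enumerate(residues):
            pos_of[r.key] = (ch, i)
    for inter in inters:
        ca, cb = pos_of.get(inter.res_a), pos_of.get(inter.res_b)
        if ca is None or cb is None or ca[0] != cb[0]:
            logger.info("skipping %s-%s: residues not in one chain", inter.res_a, inter.res_b)
            continue
        try:
            out.append(build_triad_pair(s, chains[ca[0]], ca[1], cb[1], interaction=inter))
        except IncompleteTriadError as exc:
            logger.info("skipping %s-%s: %s", inter.res_a, inter.res_b, exc)
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def single_linkage_clusters(dist: np.ndarray, cutoff: float) -> list:
    """Flat single-linkage clusters of a square dissimilarity matrix:
    members are connected through links of dissimilarity <= cutoff.
    Returns a list of index lists (each sorted; list sorted by first index)."""
    n = dist.shape[0]
    if n == 0:
        return []
    if n == 1:
        return [[0]]
    condensed = dist[np.triu_indices(n, k=1)]
    labels = fcluster(linkage(condensed, method="single"), t=cutoff, criterion="distance")
    groups: dict = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def _triad_sort_key(t: TriadPair):
    return (t.source_id, t.keys)


def triad_distance_matrix(triads) -> np.ndarray:
    n = len(triads)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r, _, _ = triad_rmsd(triads[i], triads[j])
            d[i, j] = d[j, i] = r
    return d


def cluster_triads(triads, cutoff: float):
    """Single-linkage clusters under the main-chain triad RMSD.

    Input is first put into deterministic order (source id, residue keys);
    the representative of each cluster is its first member in that order.
    Returns ``(clusters, representatives)`` where each representative carries
    its cluster size.
    """
    if cutoff <= 0:
        raise TriadmutError("clustering cutoff must be positive")
    triads = sorted(triads, key=_triad_sort_key)
    if not triads:
        return [], []
    groups = single_linkage_clusters(triad_distance_matrix(triads), cutoff)
    clusters = [[triads[i] for i in g] for g in groups]
    reps = [replace(c[0], cluster_size=len(c)) for c in clusters]
    return clusters, reps


# ---------------------------------------------------------------------------
# database
# ---------------------------------------------------------------------------

@dataclass
class TriadDatabase:
    """Searchable set of triad-pair representatives plus optional signature
    artifacts (filled by the signatures module)."""
    representatives: list = field(default_factory=list)
    cluster_cutoff: float = 0.5
    signature_params: object = None     # signatures.SignatureParams
    signature_matrix: np.ndarray | None = None   # (n_reps, n_features)
    svd_model: object = None            # signatures.SVDModel
    reduced_matrix: np.ndarray | None = None     # (n_reps, k)

    def __len__(self):
        return len(self.representatives)

    def by_id(self, rep_id: str) -> TriadPair:
        for t in self.representatives:
            if t.rep_id == rep_id:
                return t
        raise DatabaseError(f"no representative {rep_id!r} in database")

    def groups(self) -> dict:
        out = {g: [] for g in enumerate_groups()}
        for t in self.representatives:
            out[t.group].append(t)
        return out

    def group_counts(self) -> dict:
        return {g: len(v) for g, v in self.groups().items()}

    def index(self) -> pd.DataFrame:
        rows = []
        for t in self.representatives:
            inter = t.interaction
            rows.append({
                "rep_id": t.rep_id,
                "source_id": t.source_id,
                "group": t.group,
                "category": t.category,
                "name_n": t.pair_names[0],
                "name_np": t.pair_names[1],
                "kind": inter.kind if inter else "",
                "atom_a": inter.atom_a if inter else "",
                "atom_b": inter.atom_b if inter else "",
                "distance": inter.distance if inter else np.nan,
                "cluster_size": t.cluster_size,
                "keys": json.dumps([list(k) for k in t.keys]),
            })
        return pd.DataFrame(rows, columns=[
            "rep_id", "source_id", "group", "category", "name_n", "name_np",
            "kind", "atom_a", "atom_b", "distance", "cluster_size", "keys"])


def build_database(paths, cutoff: float = 0.5, chain: str | None = None) -> TriadDatabase:
    """Detect interactions in each input structure, extract triad pairs,
    cluster per category, and assemble the representative database.

    Input order does not matter: files are processed in sorted order and
    triads are deterministically ordered before clustering.
    """
    by_category: dict = {}
    for path in sorted(Path(p) for p in paths):
        s = read_structure(path, chain=chain)
        inters = detect_sidechain_interactions(s)
        for t in extract_triad_pairs(s, inters):
            by_category.setdefault(t.category, []).append(t)
    reps = []
    for cat in sorted(by_category):
        _, cat_reps = cluster_triads(by_category[cat], cutoff)
        reps.extend(cat_reps)
    if not reps:
        logger.warning("no triad pairs extracted: database is empty")
    return TriadDatabase(representatives=reps, cluster_cutoff=cutoff)


# ---------------------------------------------------------------------------
# persistence: PDB fragments + TSV index + plain-text signature artifacts
# ---------------------------------------------------------------------------

def _fragment_filename(i: int) -> str:
    return f"rep{i:05d}.pdb"


def _triad_to_structure(t: TriadPair) -> Structure:
    s = Structure(id=t.source_id.split(":")[0] or "frag")
    order = sorted(range(6), key=lambda i: t.keys[i])
    site_of_key = {t.keys[1]: 0, t.keys[4]: 1}
    for i in order:
        key = t.keys[i]
        res = Residue(chain_id=key[0], seq_number=key[1], insertion_code=key[2],
                      res_name=t.res_names[i])
        for j, name in enumerate(BACKBONE_ATOMS):
            res.add_atom(Atom(name=name, element=element_of(name),
                              coords=t.backbone_coords[4 * i + j]))
        if key in site_of_key:
            for a in t.sidechain_atoms:
                if a.site == site_of_key[key]:
                    res.add_atom(Atom(name=a.name, element=a.element,
                                      coords=np.asarray(a.coords)))
        s.add_residue(res)
    return s


def _triad_from_structure(s: Structure, row) -> TriadPair:
    keys = [tuple(k) for k in json.loads(row["keys"])]
    coords, names, sidechains = [], [], []
    site_of_key = {tuple(keys[1]): 0, tuple(keys[4]): 1}
    for i, key in enumerate(keys):
        res = s.get_residue(key)
        if res is None:
            raise DatabaseError(f"fragment for {row['rep_id']} lacks residue {key}")
        names.append(res.res_name)
        for name in BACKBONE_ATOMS:
            atom = res.get(name)
            if atom is None:
                raise DatabaseError(f"fragment for {row['rep_id']} lacks atom {key}/{name}")
            coords.append(atom.coords)
        if key in site_of_key:
            for a in res.sidechain_atoms():
                sidechains.append(SidechainAtom(site=site_of_key[key], name=a.name,
                                                element=a.element, coords=tuple(a.coords)))
    kind = row["kind"] or None
    inter = None
    if kind:
        inter = Interaction(kind=kind, res_a=keys[1], res_b=keys[4],
                            res_name_a=names[1], res_name_b=names[4],
                            atom_a=row["atom_a"], atom_b=row["atom_b"],
                            distance=float(row["distance"]))
    return TriadPair(source_id=row["source_id"], keys=tuple(keys),
                     res_names=tuple(names), backbone_coords=np.asarray(coords),
                     sidechain_atoms=tuple(sidechains), interaction=inter,
                     cluster_size=int(row["cluster_size"]))


def save_database(db: TriadDatabase, directory) -> None:
    """Persist a database: one PDB fragment per representative, a TSV index,
    and (if fitted) plain-text signature matrix and SVD model."""
    directory = Path(directory)
    (directory / "fragments").mkdir(parents=True, exist_ok=True)
    index = db.index()
    index.insert(0, "fragment", [_fragment_filename(i) for i in range(len(db))])
    index.to_csv(directory / "index.tsv", sep="\t", index=False)
    for i, t in enumerate(db.representatives):
        write_structure(_triad_to_structure(t), directory / "fragments" / _fragment_filename(i))
    meta = {"cluster_cutoff": db.cluster_cutoff, "n_representatives": len(db)}
    if db.signature_params is not None:
        meta["signature_params"] = db.signature_params.as_dict()
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    if db.signature_matrix is not None:
        np.savetxt(directory / "signatures.tsv", db.signature_matrix, fmt="%d", delimiter="\t")
    if db.svd_model is not None:
        from .signatures import save_svd_model
        save_svd_model(db.svd_model, directory)
    if db.reduced_matrix is not None:
        np.savetxt(directory / "reduced.tsv", db.reduced_matrix, delimiter="\t")


def load_database(directory) -> TriadDatabase:
    """Inverse of :func:`save_database`; errors name the offending file/row."""
    directory = Path(directory)
    index_path = directory / "index.tsv"
    if not index_path.exists():
        raise DatabaseError(f"missing index file {index_path}")
    meta = json.loads((directory / "meta.json").read_text())
    index = pd.read_csv(index_path, sep="\t", dtype={"kind": str, "atom_a": str, "atom_b": str},
                        keep_default_na=False, na_values=[])
    reps = []
    for _, row in index.iterrows():
        frag = directory / "fragments" / row["fragment"]
        if not frag.exists():
            raise DatabaseError(f"missing fragment file {frag}")
        try:
            s = read_structure(frag)
            reps.append(_triad_from_structure(s, row))
        except (TriadmutError, ValueError, KeyError) as exc:
            raise DatabaseError(f"corrupt index row for {row.get('rep_id', '?')}: {exc}") from exc
    db = TriadDatabase(representatives=reps, cluster_cutoff=float(meta["cluster_cutoff"]))
    sig_path = directory / "signatures.tsv"
    if "signature_params" in meta and sig_path.exists():
        from .signatures import SignatureParams, load_svd_model
        db.signature_params = SignatureParams(**meta["signature_params"])
        db.signature_matrix = np.loadtxt(sig_path, delimiter="\t", ndmin=2)
        if (directory / "svd_model.json").exists():
            db.svd_model = load_svd_model(directory)
        red_path = directory / "reduced.tsv"
        if red_path.exists():
            db.reduced_matrix = np.loadtxt(red_path, delimiter="\t", ndmin=2)
    return db
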