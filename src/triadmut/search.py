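"""The search engine: enumerate candidate residue pairs in a target chain,
match their triad pairs against the template database, graft template side
chains, screen steric clashes, and emit mutation proposals.

A residue pair is a mutation target when its alpha carbons are 3.35–16.40 Å
apart (the Cα range observed across interacting pairs in the template
database), the residues are not sequence neighbours (separation >= 3 so the
two triads share no residue), both triads are complete, and the pair does not
already form a database-side interaction.  Each surviving template match with
main-chain RMSD <= 0.5 Å (default) becomes a proposal: the template pair's
identities at the target sites, with the template side chains transplanted
through the superposition transform and screened for clashes at 2 Å.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .chem import (AROMATIC_RESIDUES, BACKBONE_ATOMS, HYDROPHOBIC_RESIDUES,
                   NEGATIVE_RESIDUES, POSITIVE_RESIDUES, THREE_TO_ONE, element_of)
from .errors import ConfigError, IncompleteTriadError, ProvenanceError, TriadmutError
from .interactions import pair_interacts
from .signatures import compute_signature, filter_candidates, reduce_signature
from .structure import Atom, Structure
from .superpose import PAIRING_DIRECT, kabsch_superpose, triad_rmsd
from .triads import TriadPair, build_triad_pair

logger = logging.getLogger(__name__)


@dataclass
class SearchParams:
    """All thresholds of one search run (defaults are the published values)."""
    ca_min: float = 3.35
    ca_max: float = 16.40
    rmsd_threshold: float = 0.5
    clash_cutoff: float = 2.0
    region_center: tuple | None = None   # residue key
    region_radius: float = 10.0
    ssv_cutoff: float = math.inf
    min_seq_separation: int = 3

    def __post_init__(self):
        if not 0 < self.ca_min < self.ca_max:
            raise ConfigError("require 0 < ca_min < ca_max")
        if self.rmsd_threshold <= 0 or self.clash_cutoff <= 0:
            raise ConfigError("rmsd_threshold and clash_cutoff must be positive")
        if self.min_seq_separation < 3:
            raise ConfigError("min_seq_separation below 3 would let triads share residues")


@dataclass
class MutationProposal:
    """One suggested simultaneous double substitution."""
    site_a: tuple                 # residue key of the lower-numbered site
    site_b: tuple
    wild_a: str                   # three-letter codes
    wild_b: str
    proposed_a: str
    proposed_b: str
    template_id: str              # representative id in the database
    template_source: str
    template_pair_names: tuple
    rmsd: float
    pairing: str
    clash: bool = False
    clash_pairs: tuple = ()
    categories: frozenset = frozenset()

    @property
    def notation(self) -> str:
        def one(site, wild, prop):
            label = f"{site[1]}{site[2]}".strip()
            return f"{THREE_TO_ONE.get(wild, 'X')}{label}{THREE_TO_ONE.get(prop, 'X')}"
        return f"{one(self.site_a, self.wild_a, self.proposed_a)}/" \
               f"{one(self.site_b, self.wild_b, self.proposed_b)}"


def label_pair(name_a: str, name_b: str) -> frozenset:
    """Category labels of a proposed residue pair, from a fixed property
    table (HIS counts as both positive and aromatic)."""
    labels = set()
    for n in (name_a, name_b):
        if n in POSITIVE_RESIDUES:
            labels.add("positive")
        if n in NEGATIVE_RESIDUES:
            labels.add("negative")
        if n in AROMATIC_RESIDUES:
            labels.add("aromatic")
        if n in HYDROPHOBIC_RESIDUES:
            labels.add("hydrophobic")
    if name_a == "CYS" and name_b == "CYS":
        labels.add("disulfide")
    return frozenset(labels)


def label_proposal(prop: MutationProposal) -> frozenset:
    return label_pair(prop.proposed_a, prop.proposed_b)


def _single_chain(s: Structure):
    chains = s.chains()
    if len(chains) != 1:
        raise TriadmutError(
            f"search expects a single-chain structure, got chains {sorted(chains)}")
    return next(iter(chains.values()))


def enumerate_target_pairs(s: Structure, params: SearchParams | None = None):
    """Candidate (pos_i, pos_j, TriadPair) tuples for one cleaned chain."""
    params = params or SearchParams()
    residues = _single_chain(s)
    n = len(residues)
    ca = np.full((n, 3), np.nan)
    for i, r in enumerate(residues):
        if r.ca is not None:
            ca[i] = r.ca.coords

    center_ca = None
    if params.region_center is not None:
        cres = s.get_residue(params.region_center)
        if cres is None or cres.ca is None:
            raise TriadmutError(f"region centre residue {params.region_center} not found")
        center_ca = cres.ca.coords

    out = []
    for i in range(n):
        if np.isnan(ca[i]).any():
            continue
        for j in range(i + params.min_seq_separation, n):
            if np.isnan(ca[j]).any():
                continue
            d = float(np.linalg.norm(ca[i] - ca[j]))
            if not (params.ca_min <= d <= params.ca_max):
                continue
            if center_ca is not None:
                if (np.linalg.norm(ca[i] - center_ca) > params.region_radius
                        and np.linalg.norm(ca[j] - center_ca) > params.region_radius):
                    continue
            if pair_interacts(residues[i], residues[j]):
                continue
            try:
                triad = build_triad_pair(s, residues, i, j)
            except IncompleteTriadError:
                continue
            if residues[i].res_name == "PRO" or residues[j].res_name == "PRO":
                logger.info("target pair %s-%s includes a proline site (constrained backbone)",
                            residues[i].label, residues[j].label)
            out.append((i, j, triad))
    return out


@dataclass
class SearchCounts:
    """Stage counts of one search run (enumerated >= filtered >= passing)."""
    pairs_enumerated: int = 0
    alignments_after_filter: int = 0
    proposals: int = 0


def propose_mutations(s: Structure, db, params: SearchParams | None = None,
                      check_clash: bool = True, counts: SearchCounts | None = None):
    """All double-substitution proposals for one target structure.

    For each candidate pair: signature pre-filter (disabled at cutoff inf) ->
    main-chain superposition against surviving representatives -> one proposal
    per match with RMSD <= threshold.  Clashing proposals are retained and
    flagged, never dropped.  Output is sorted by (rmsd, notation, template).
    """
    params = params or SearchParams()
    targets = enumerate_target_pairs(s, params)
    if counts is not None:
        counts.pairs_enumerated = len(targets)
    if len(db) == 0:
        return []

    use_filter = not math.isinf(params.ssv_cutoff)
    if use_filter and (db.svd_model is None or db.signature_params is None):
        raise TriadmutError("finite ssv_cutoff requires a database with fitted signatures")

    proposals = []
    n_alignments = 0
    for _, _, triad in targets:
        if use_filter:
            sig = compute_signature(triad, db.signature_params)
            reduced = reduce_signature(sig, db.svd_model)
            candidate_ids = set(filter_candidates(reduced, db, params.ssv_cutoff))
            candidates = [t for t in db.representatives if t.rep_id in candidate_ids]
        else:
            candidates = db.representatives
        n_alignments += len(candidates)
        for rep in candidates:
            rmsd, _, pairing = triad_rmsd(triad, rep)
            if rmsd > params.rmsd_threshold:
                continue
            if pairing == PAIRING_DIRECT:
                prop_a, prop_b = rep.pair_names
            else:
                prop_b, prop_a = rep.pair_names
            prop = MutationProposal(
                site_a=triad.keys[1], site_b=triad.keys[4],
                wild_a=triad.res_names[1], wild_b=triad.res_names[4],
                proposed_a=prop_a, proposed_b=prop_b,
                template_id=rep.rep_id, template_source=rep.source_id,
                template_pair_names=rep.pair_names,
                rmsd=rmsd, pairing=pairing,
            )
            prop.categories = label_proposal(prop)
            if check_clash:
                mutant = graft_sidechains(s, prop, db)
                report = detect_clash(mutant, prop, params.clash_cutoff)
                prop.clash, prop.clash_pairs = report.clash, tuple(report.pairs)
            proposals.append(prop)
    if counts is not None:
        counts.alignments_after_filter = n_alignments
        counts.proposals = len(proposals)
    proposals.sort(key=lambda p: (p.rmsd, p.notation, p.template_id))
    return proposals


def summarize_by_sites(proposals):
    """Best (lowest-RMSD) proposal per (sites, substitution) combination."""
    best = {}
    for p in proposals:
        key = (p.site_a, p.site_b, p.proposed_a, p.proposed_b)
        if key not in best or p.rmsd < best[key].rmsd:
            best[key] = p
    return sorted(best.values(), key=lambda p: (p.rmsd, p.notation))


def _target_triad_for(s: Structure, prop: MutationProposal) -> TriadPair:
    residues = _single_chain(s)
    pos = {r.key: i for i, r in enumerate(residues)}
    if prop.site_a not in pos or prop.site_b not in pos:
        raise ProvenanceError(f"sites {prop.site_a}/{prop.site_b} not in structure {s.id}")
    ra, rb = residues[pos[prop.site_a]], residues[pos[prop.site_b]]
    if ra.res_name != prop.wild_a or rb.res_name != prop.wild_b:
        raise ProvenanceError(
            f"wild identities {prop.wild_a}/{prop.wild_b} do not match structure "
            f"{s.id} ({ra.res_name}/{rb.res_name}): proposal from a different structure?")
    return build_triad_pair(s, residues, pos[prop.site_a], pos[prop.site_b])


def graft_sidechains(s: Structure, prop: MutationProposal, db) -> Structure:
    """Build the mutant: both target backbones untouched, side chains (CB and
    outward) replaced by the template residues' side chains mapped through the
    superposition transform, residue names updated."""
    rep = db.by_id(prop.template_id)  # raises DatabaseError if absent
    triad = _target_triad_for(s, prop)
    rmsd, tf, pairing = triad_rmsd(triad, rep)

    # which template site lands on which target site under the used pairing
    site_map = {0: 0, 1: 1} if pairing == PAIRING_DIRECT else {0: 1, 1: 0}

    mutant = s.copy()
    mutant.id = f"{s.id}_mut_{prop.notation.replace('/', '_')}"
    for tpl_site, tgt_site in site_map.items():
        key = prop.site_a if tgt_site == 0 else prop.site_b
        res = mutant.get_residue(key)
        for name in [n for n in res.atoms if n not in BACKBONE_ATOMS]:
            del res.atoms[name]
        res.res_name = rep.pair_names[tpl_site]
        for a in rep.sidechain_atoms:
            if a.site != tpl_site:
                continue
            res.add_atom(Atom(name=a.name, element=a.element or element_of(a.name),
                              coords=tf.apply(np.asarray(a.coords))))
    return mutant


@dataclass
class ClashReport:
    clash: bool
    pairs: list = field(default_factory=list)  # ((key, atom), (key, atom), distance)


def detect_clash(mutant: Structure, prop: MutationProposal, cutoff: float = 2.0) -> ClashReport:
    """Clash iff any newly inserted side-chain atom lies closer than ``cutoff``
    to any atom outside the two mutated residues (the mutated residues' own
    atoms never count: covalent geometry is not a clash)."""
    sites = {prop.site_a, prop.site_b}
    inserted = []
    for key in sites:
        res = mutant.get_residue(key)
        if res is None:
            raise ProvenanceError(f"mutated site {key} missing from structure")
        inserted.extend(((res.key, a.name), a.coords) for a in res.sidechain_atoms())
    report = ClashReport(clash=False)
    if not inserted:
        return report
    env_ids, env_xyz = [], []
    for res in mutant:
        if res.key in sites:
            continue
        for a in res.atoms.values():
            env_ids.append((res.key, a.name))
            env_xyz.append(a.coords)
    if not env_xyz:
        return report
    env_xyz = np.asarray(env_xyz)
    for aid, xyz in inserted:
        d = np.linalg.norm(env_xyz - xyz, axis=1)
        for j in np.where(d < cutoff)[0]:
            report.pairs.append((aid, env_ids[j], float(d[j])))
    report.clash = bool(report.pairs)
    return report
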