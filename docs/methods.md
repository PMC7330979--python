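# Methods

## The model

`triadmut` proposes pairs of simultaneous point mutations that introduce a new
side-chain–side-chain interaction into a target protein, justified by
templates mined from known structures. The working hypothesis is geometric:
if two non-interacting residues of the target sit on a main-chain scaffold
that is (nearly) identical to the scaffold of an *interacting* residue pair
observed in a real structure, then substituting the target pair by the
observed pair should recreate the interaction without disturbing the fold,
and may stabilize it.

The unit of storage and comparison is the **triad pair**: the two interacting
residues n and n′ plus their sequence flanks n−1, n+1, n′−1, n′+1. Similarity
between triad pairs is the root-mean-square deviation over a fixed 24-atom
main-chain correspondence — residues in the order (n−1, n, n+1, n′−1, n′,
n′+1), atoms (N, CA, C, O) within each residue —

    RMSD = sqrt( (1/N) Σᵢ |δᵢ|² ),    N = 24,

minimized over proper rigid motions (sign-corrected Kabsch; a mirror-image
solution is chemically invalid and explicitly excluded). Because the two
residues of an interaction are unordered, both pairings of the target pair
onto the template (direct and swapped) are evaluated and the better one used;
missing the swapped match would halve sensitivity.

## Database construction

Templates are seeded by three interaction types detected between side-chain
atoms only, with fixed atom lists and strict distance cutoffs:

| type          | cutoff   | atoms |
|---------------|----------|-------|
| hydrogen bond | < 3.50 Å | ARG NE/NH1/NH2, ASN ND2/OD1, ASP OD1/OD2, GLN NE2/OE1, LYS NZ, GLU OE1/OE2, HIS ND1/NE2, SER OG, THR OG1, TRP NE1, TYR OH |
| ionic         | < 6.00 Å | positive: ARG CZ; HIS CD2/CE1/CG — negative: ASP CG/OD1/OD2; GLU CD |
| disulfide     | < 2.08 Å | CYS SG |

The table is implemented verbatim even where it surprises (LYS NZ may
hydrogen-bond but is absent from the ionic list; HIS contributes ring
carbons): these lists define database content, and "correcting" them would
silently change what the database stores. Ionic detection requires one atom
from each charge group — the only chemically coherent reading of a table that
lists atoms without roles. Whether two acceptor-only atoms may count as a
hydrogen bond is not resolvable from the atom lists alone; any listed-atom
pair within the cutoff is accepted, which is the permissive reading.

Intra-residue and sequence-adjacent (|Δseq| ≤ 1) pairs are never counted.
One triad pair is extracted per detected interaction; interactions whose six
residues are not all present with complete backbones are skipped with a
logged reason. Within each storage category, triad pairs are deduplicated by
single-linkage clustering under the main-chain triad RMSD (side chains
excluded from the distance so one representative generalizes across
side-chain conformers). The default clustering cutoff is 0.5 Å, the midpoint
of the empirically useful 0.3–0.9 Å range; it is exposed in the
configuration. The representative of a cluster is its first member under a
deterministic ordering (source id, then residue keys), so identical input
sets produce byte-identical databases regardless of file order.

Storage layout: 122 categories — ordered (first residue × partner) pairs over
the 11 polar residue types (11 × 11 = 121) plus one disulfide category — and
12 groups keyed by the first residue type (the 11 polar types plus CYS, the
CYS group holding only CYS–CYS disulfides). "First" means the lower author
residue number in the source structure. Persistence is flat files: one
PDB-format fragment per representative, a TSV index, and plain-text signature
artifacts; a relational backend is a deployment detail, not an algorithmic
one.

## Search

Candidate sites in the target are residue pairs whose Cα–Cα distance lies in
[3.35, 16.40] Å (the Cα range spanned by interacting pairs in template
databases), with sequence separation ≥ 3 so that the two triads never share a
residue, complete triads on both sides, and no pre-existing database-side
interaction between them ("not in direct contact"; evaluation-type contacts
such as hydrophobic packing do not exclude a pair). Wild-site identities are
unrestricted — nonpolar sites are legitimate targets — though a proline site
is logged as a warning since its backbone φ is constrained. An optional
region search keeps only pairs with at least one Cα within 10 Å of a query
residue (the inclusive reading, which maximizes recall).

Each candidate triad is compared against the database; matches with RMSD
below 0.5 Å (default) become proposals carrying the template identities, the
winning pairing, the RMSD, clash status and category labels. Proposals are
deterministically sorted (RMSD, then notation). Multiple templates proposing
the same substitution at the same sites are all emitted; a per-site summary
keeping the best RMSD per (sites, substitution) is emitted alongside.

### Signature pre-filter

Comparing every target triad against every representative is wasteful, so a
fingerprint filter can prune candidates before superposition. The fingerprint
is a cumulative cutoff-scanning vector: atoms are typed into 8 pharmacophore
classes (hydrophobic, aromatic, positive, negative, donor, acceptor, sulfur,
neutral; multi-class membership allowed; the typing table ships with the code
and is versioned), and for each unordered class pair and each cumulative
cutoff from 0 to 10 Å in 0.1 Å steps the entry counts atom pairs at or below
that distance (36 class pairs × 100 bins = 3600 features with the default
table; vector length is a derived property of the parameters, not a
constant). The database's signature matrix is factored by SVD, A = U S Vᵀ,
and the retained dimensionality k is the smallest number of leading singular
values reaching 70% of the spectrum sum (the literal reading; a squared
"variance" criterion is available as a configuration switch). New vectors are
reduced by right-singular projection x ↦ x V_k — stated explicitly because
projection conventions differ — and compared by Euclidean distance on raw
counts (no normalisation).

The filter is a pre-filter, never a verdict: the RMSD gate always decides.
Published full-scale calibrations of such filters (a distance cutoff of 13)
depend on the original feature scaling and do not transfer to other typings
or database sizes, so the default here is ∞ (filter off) and a calibration
helper reports the smallest lossless cutoff on a given database — the largest
reduced-signature distance of any match the RMSD search confirms.

## Grafting and clash screening

A proposal is realised by transplanting the template pair's side-chain atoms
(CB and outward) onto the target through the superposition transform; the
target's 24 main-chain atoms are untouched by construction, residue names are
updated, and all other residues are left alone. A steric clash is flagged
when any newly inserted atom lies closer than 2 Å to any atom *outside* the
two mutated residues — the mutated residues' own atoms are excluded because
covalent geometry must not count as a clash. Clashing proposals are retained
and flagged rather than dropped, so a downstream filter can hide or sort
them; no rotamer optimization or energy minimization is attempted.

## Evaluation

Wild and mutant structures are compared by seven inter-residue contact types
counted on heavy atoms: hydrogen bond (donor–acceptor ≤ 3.5 Å with a ≥ 90°
angle at the donor), weak hydrogen bond (C–H donor to acceptor ≤ 3.6 Å,
donor angle within 30–150°), polar and weak polar (the same distances without
the angle criteria), ionic (opposing formal-charge groups ≤ 4.0 Å), aromatic
(ring atoms ≤ 4.5 Å or ring centroids ≤ 6.0 Å), and hydrophobic (apolar
atoms ≤ 4.5 Å, i.e. carbons not bonded to N/O/S plus the MET sulfur, from a
shipped typing table). Since cleaned structures carry no hydrogens, donor
angles are measured at the donor using its bonded heavy-atom antecedent(s) —
a documented approximation to hydrogen-explicit geometry whose exact angle
conventions cannot be reproduced without protons. One deliberate resolution:
a hydrogen-bond distance window wider than the polar window would break the
invariant HB ⊆ polar that the definitions imply, so both use 3.5 Å and the
angle criterion alone separates them (likewise 3.6 Å for the weak pair).

Per contact type, the headline accuracy is the fraction of mutants whose
count increased or stayed equal (Δ ≥ 0); strict-increase and
"reduced or kept" (Δ ≤ 0) accuracies are reported alongside — the latter is
the expected direction for hydrophobic contacts, since proposals substitute
polar pairs. Significance uses the classic paired t-test on per-structure
totals, one-tailed, with the direction an explicit argument; zero-variance
differences raise an error instead of reporting a fabricated p-value. No
multiple-testing correction is applied.

## Synthetic fixtures and what they do (not) show

The generator builds ideal single-chain backbones from standard bond geometry
(helix φ ≈ −57°, ψ ≈ −47°; strand φ ≈ −120°, ψ ≈ +120°), alanine side chains
everywhere, and *planted* interactions: the side-chain atoms of a chosen pair
(CYS SG–SG at 2.0 Å, SER OG–THR OG1 at 3.0 Å, or ARG CZ–ASP OD1 at 4.5 Å by
default) placed on the Cβ–Cβ axis so the requested interaction is detected.
A seeded coordinate jitter (σ = 0.02 Å, roughly coordinate-precision scale)
makes distinct seeds give distinct structures while the same spec and seed
reproduce identical coordinates. Plants are feasible only when the Cβ
separation can host the atoms at sane bond-ish distances (0.8–4.5 Å arms);
on an ideal strand, sequence separations ≥ 3 put Cβ atoms too far apart for
any of the planted types, so the recovery benchmark uses helices.

The planted-recovery benchmark takes each fixture with a planted interaction
as a template, strips the interacting pair of the *same* structure to alanine
backbones, applies a random rigid motion, and requires the search to recover
the template identities at numerically zero RMSD (each case against its own
single-template database: a shared database would correctly deduplicate the
near-identical ideal-helix triads across cases and leave nothing to recover —
itself evidence the clustering works). Passing this suite shows the geometry
engine, pairing logic, filter and grafting are internally exact; it does not
show that proposals on real, irregular backbones are biologically useful, nor
exercise altloc/insertion-code pathology at scale, crystal contacts, or
multi-chain interfaces.

## Numerical choices and degenerate inputs

* Superposition requires ≥ 3 points and rejects collinear sets (relative
  second singular value < 1e-8) as ill-conditioned.
* Altloc resolution keeps the highest occupancy, ties broken by file order.
  Non-standard residues (MSE etc.) are dropped with a warning; hydrogens and
  waters always; only the first model of multi-model files is read.
* Clustering of n ≤ 1 triads is trivial; flat single-linkage clusters at
  cutoff t equal connected components of the ≤ t graph, which holds for any
  symmetric dissimilarity (the min-over-pairings triad RMSD need not satisfy
  the triangle inequality).
* An all-zero signature matrix has a degenerate spectrum and is rejected;
  k is clamped to the numerical rank.
* Fragment reload identifies flanks by the stored six residue keys, not by
  inference from numbering, so gapped author numbering round-trips.

## Limitations

* Contact counts are atom-pair counts under fixed typing tables; they are
  internally consistent between wild and mutant but not comparable in
  absolute value to hydrogen-explicit contact tools.
* The 2 Å clash test is a hard-sphere screen; it neither scales by element
  nor considers the possibility of side-chain rearrangement.
* ΔΔG prediction is out of scope; the output reserves a pass-through column
  for an external predictor but never computes one.
* Database construction at full archive scale is the same code path but is
  only exercised at fixture scale here; resolution/quality filtering of
  source structures is not applied by default.
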