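# triadmut

Propose stabilizing **double mutations** for a protein structure by matching
backbone-conserved **triad-pair templates** mined from known structures.

## The problem

Single-point stabilizing mutations are hard enough to predict; *pairs* of
simultaneous substitutions that create a new side-chain interaction (a
hydrogen bond, salt bridge, or disulfide) are combinatorially worse. The idea
implemented here sidesteps energy prediction: if two non-interacting residues
of a target protein sit on the same main-chain scaffold as an *interacting*
pair observed in a real structure, the observed pair is a geometrically
proven conformation — swap it in, keep the backbone, and the interaction
should form.

The unit of comparison is the **triad pair**: interacting residues n and n′
plus their sequence flanks n−1, n+1, n′−1, n′+1. Two triad pairs match when
the RMSD over their 24 main-chain atoms — (n−1, n, n+1, n′−1, n′, n′+1) ×
(N, Cα, C, O) —

&nbsp;&nbsp;&nbsp;&nbsp;RMSD = √( (1/N) Σᵢ δᵢ² ),&nbsp;&nbsp;N = 24,

is below 0.5 Å after optimal rigid superposition (sign-corrected Kabsch, both
pairings of the unordered residue pair tried). The pipeline:

1. **Database**: detect side-chain hydrogen bonds (< 3.50 Å), ionic contacts
   (< 6.00 Å) and disulfides (< 2.08 Å) in template structures via fixed atom
   lists; extract triad pairs; deduplicate by single-linkage clustering under
   the main-chain RMSD; store representatives in 122 residue-pair categories
   grouped into 12 first-residue databases.
2. **Search**: enumerate target residue pairs with Cα–Cα distance in
   3.35–16.40 Å, sequence separation ≥ 3, complete triads, and no existing
   interaction; optionally prune templates by an SVD-reduced cutoff-scanning
   fingerprint (Euclidean distance on A = U S Vᵀ projections keeping 70% of
   the spectrum); confirm matches by the 24-atom RMSD.
3. **Graft & screen**: transplant the template side chains through the
   superposition transform (backbone untouched), flag proposals placing any
   new atom within 2 Å of the neighbourhood as steric clashes.
4. **Evaluate**: count seven inter-residue contact types (hydrogen bond, weak
   HB, ionic, aromatic, polar, weak polar, hydrophobic) in wild and mutant,
   report per-type accuracies and a paired one-tailed t-test.

See `docs/methods.md` for the model, parameter tables, and limitations.

## Worked example

Everything is testable offline: the package ships a generator for synthetic
PDB structures with planted interactions. Build a one-template database from
a helical fixture carrying a planted SER–THR hydrogen bond, then search a
target with the same backbone but plain alanines:

```bash
triadmut fixtures --n-residues 16 --plant 4,8,hydrogen_bond --seed 3 --out template.pdb
triadmut fixtures --n-residues 16 --seed 3 --out target.pdb
triadmut build-db --out db template.pdb
triadmut search --pdb target.pdb --chain A --db db --out proposals.tsv
```

which prints

```
1 representatives written to db
  SER: 1
60 pairs enumerated, 60 alignments, 10 proposals -> proposals.tsv
```

and the top of `proposals.tsv` reads

```
Mutation   Template    Chain  R1   R2   RMSD    ddG  Clash  Categories
A4S/A8T    template:A  A      SER  THR  0.0          0
A3S/A7T    template:A  A      SER  THR  0.0545       0
A7S/A11T   template:A  A      SER  THR  0.055        0
```

Read the first row as: mutate Ala4→Ser and Ala8→Thr, justified by the
template's SER–THR pair, whose six-residue main chain overlaps the target's
at 0.0 Å RMSD (it is the same backbone — the planted pair is recovered
exactly); no steric clash. The other rows are helix positions one turn away,
where the main chain still matches within a few hundredths of an Ångström —
exactly the kind of near-degenerate alternatives a periodic backbone should
produce. `triadmut run` chains database construction, search, grafting,
clash screening and contact evaluation into one command; the library API
(`triadmut.propose_mutations`, `triadmut.graft_sidechains`, ...) exposes each
stage.

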