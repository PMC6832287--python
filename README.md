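# s1scape

Cross-kingdom comparison toolkit for S1/OB-fold protein domains. Given a
plain-text registry of domain slices (PDB id, chain, author residue range,
kingdom), the pipeline computes:

- **sequence identity matrices** from global Needleman–Wunsch/Gotoh alignment
  (affine gaps, BLOSUM62 by default), with extrema that skip same-protein
  pairs;
- **progressive multiple alignments**, per-column information content
  (sequence-logo matrices) and conserved-position calls;
- **rigid-body superposition RMSD** (Kabsch via SVD, sequence-guided CA
  correspondence), pairwise and group-wise with a medoid reference;
- **radius of gyration** (unweighted, non-hydrogen atoms);
- **per-residue flexibility**: three-class labels from predicted fluctuation
  tables (rigid < 3 Å, moderate 3–6 Å, flexible > 6 Å) or from within-domain
  B-factor z-scores (flexible at z > 1), with percent-flexible summaries;
- **order/disorder-promoting composition** and **Kruskal–Wallis** cross-group
  tests (tie-corrected H, chi-square or permutation p);
- **UPGMA dendrograms** from identity distances, written as Newick.

A synthetic-fixture generator (`s1scape.synthetic`) produces PDB files with
exactly known radius of gyration, flexible-residue counts and pairwise
sequence identity, so the entire pipeline is testable offline.

## CLI

```bash
s1scape registry validate            # check the bundled 24-entry registry
s1scape fetch --dest data/structures # download registry PDB entries (network!)
s1scape extract  --structures data/structures        # write domain slices
s1scape identity --structures data/structures        # identity matrix + extrema
s1scape superpose --structures data/structures --kingdom bacteria
s1scape rg --structures data/structures
s1scape flex --structures data/structures
s1scape composition --structures data/structures
s1scape kw --structures data/structures --variable rg
s1scape tree --structures data/structures --out tree.nwk
s1scape report --structures data/structures --out report/
s1scape simulate --out toy.pdb --target-rg 12.0 --flexible-fraction 0.3
```

`fetch` is the only networked command; everything else is offline. A custom
registry (tab-separated: `pdb_id chain start end kingdom protein_name
[group]`) can be passed to any command with `--registry`.

## Layout

| module | purpose |
| --- | --- |
| `s1scape.registry` | registry records, validation, kingdom partition |
| `s1scape.structure` | PDB parsing, domain slicing, sequences, CA coordinates |
| `s1scape.seqcompare` | Gotoh aligner, identity matrices, progressive MSA, logos |
| `s1scape.structcompare` | Kabsch superposition, RMSD matrices, radius of gyration |
| `s1scape.flex` | fluctuation/B-factor flexibility profiles |
| `s1scape.composition` | order/disorder composition, Kruskal–Wallis |
| `s1scape.phylo` | UPGMA / neighbor-joining, Newick I/O |
| `s1scape.synthetic` | ground-truth fixture generators |
| `s1scape.pipeline`, `s1scape.cli` | orchestration and command line |
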