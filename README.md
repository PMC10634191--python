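# edt — relative divergence-time graphs of evolutionary scenarios

`edt` works with *relaxed scenarios*: a dated gene tree reconciled with a
dated species tree under time-consistency axioms, with no ancestrality
constraint on the reconciliation map. Comparing, for every pair of extant
genes, the stamp of their gene-tree last common ancestor with the stamp of
the species-tree last common ancestor of their species yields a 3-partition
of all gene pairs into **later** (LDT), **equal** (EDT) and **prior** (PDT)
divergence-time graphs.

The package provides:

- **trees** — planted phylogenetic trees, ancestor order (extended to
  edges), lca, restriction, triple display, time maps, Newick I/O;
- **scenario** — relaxed scenarios with exhaustive axiom checking (S0–S3),
  restricted-scenario axioms (S4–S6: fully witnessed, speciation
  constraints), HGT labeling, witnesses, genericity;
- **divergence** — the EDT/LDT/PDT 3-partition of a scenario, restriction,
  proper-coloring and cograph tests (with induced-P4 certificates), and a
  structural report (rainbow triangles, longest induced EDT path, odd-hole
  freeness — exhaustive searches behind explicit size guards);
- **triples** — informative/forbidden rooted triples on genes and on
  species read off a 3-partition, the BUILD consistency test, and a
  mixed required+forbidden tree construction;
- **builder** — construction of a relaxed scenario explaining any valid
  3-partition, with a modified child-choice rule that additionally yields a
  restricted scenario; a user-supplied species tree agreeing with the
  species triples is used unchanged;
- **recognition** — the explainability verdict for 3-partitions, and
  certificate-producing recognizers for PDT graphs, LDT graphs and EDT
  graphs of HGT-free scenarios, plus a budgeted exhaustive oracle for
  small general EDT instances (the general problem is NP-complete);
- **orthology** — weak/strict (quasi-)orthology graphs and the symmetrized
  Fitch graph of a scenario;
- **simulate** — a deterministic generator of valid scenarios (the test
  bed for all property suites) and canonical worked-example fixtures.

## Command line

```sh
# simulate a scenario and validate it
edt simulate --species 5 --genes 12 --transfer 0.3 --dup 0.2 --seed 7 --out scen.json
edt check scen.json

# compute its 3-partition, then reconstruct an explaining scenario
edt partition scen.json --out part.tsv
edt build part.tsv --restricted --out explained.json

# recognize a colored graph (TSV with a '#colors' header block)
edt recognize pdt graph.tsv --out certificate.json
edt recognize edt-hgtfree graph.tsv
edt recognize edt-small graph.tsv      # exhaustive, small instances only

# orthology-variant graphs
edt orthology scen.json --which strict-quasi
```

`edt build` exits non-zero naming the first failed explainability
condition (proper colorings, cograph tests, triple consistency) on invalid
input. File formats: scenario JSON bundles (trees as Newick with explicit
inner-vertex ids, exact rational stamps), colored-graph / 3-partition TSV
(`u<TAB>v<TAB>{LT|EQ|GT}`, every pair classified).

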