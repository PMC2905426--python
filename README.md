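# karyophy

Chromosomal phylogenetics from cross-species chromosome-painting homology
maps, built around the comparative cytogenetics of the pitheciine New
World monkeys (*Pithecia irrorata*, PIR; *Cacajao calvus rubicundus*,
CCR; *Chiropotes utahicki*, CUT).

In a chromosome-painting (ZOO-FISH) experiment, whole-chromosome probes
of one species are hybridised onto metaphases of another; every
contiguous painted block is one **hybridisation signal**, and a target
chromosome carrying material of two or more probe chromosomes is a
**syntenic association** (written `3/20/15/14`). karyophy takes such
homology maps — plain TSV tables, one row per probe chromosome — and
computes the full analysis chain:

1. **Synteny analysis** — signal counts per haploid set, conserved-synteny
   classes (WHOLE / ASSOCIATED / SPLIT per probe chromosome), association
   detection, and matching against the inferred ancestral Platyrrhini
   association catalogue (3a/21, 5/7a, 2b/16b, 8a/18, 14/15a, 10a/16a).
2. **Character coding** — presence (1) / absence (0) of discrete
   chromosomal characters (retained associations, fusion/fission and
   inversion products) into a binary matrix with `?` for unknowns;
   NEXUS (`symbols="01" missing=?`) and TSV serialisation.
3. **Maximum parsimony** — Fitch small parsimony over all (2n−5)!!
   unrooted binary topologies (exhaustive search, capped at 10 taxa),
   with tree length *s*, its conceivable bounds *m* (sum over characters
   of observed states − 1) and *g* (sum of min(n₀, n₁)), and the indices

       CI = m/s,    RI = (g − s)/(g − m),    HI = 1 − CI,

   outgroup rooting, character-resampling bootstrap and majority-rule
   consensus.
4. **Simulation** — binary characters evolved by a symmetric per-branch
   flip process, and karyotypes evolved by typed rearrangements (centric
   fusion/fission, pericentric/paracentric inversion, tandem fusion,
   sex-autosome translocation), with end-to-end recovery experiments.

The package ships transcriptions of the published homology maps (human
probes on PIR and CCR, *Saguinus oedipus* probes on CCR; SHA-256-pinned),
a documented synthetic reconstruction of the CUT map, the six-form
ancestral catalogue, and a documented 5-taxon character matrix for the
three pitheciines plus the outgroups *Brachyteles arachnoides* (BAR) and
*Cebus apella* (CAP).

## Worked example

```python
>>> from karyophy import fixtures as fx, count_signals, detect_associations, match_ancestral
>>> pir = fx.load_hsa_pir()                      # human probes on P. irrorata
>>> count_signals(pir).total_autosomal
32
>>> for m in match_ancestral(detect_associations(pir), fx.ancestral_catalogue()):
...     print(m.catalogue_form.label, "->", "PIR", m.target_chrom, m.matched_form.label)
3a/21 -> PIR 19 21/3
5/7a -> PIR 1 7/5
2b/16b -> PIR 4 16/2
8a/18 -> PIR 7 8/18
14/15a -> PIR 13 15/14
10a/16a -> PIR 6 16/10/16/10
```

The 32 is the number of hybridisation signals the 22 human autosomal
probes produce per haploid PIR set; the six ancestral Platyrrhini
associations are all retained, the last one in the inverted, interleaved
`16/10/16/10` arrangement produced by a pericentric inversion of the
ancestral 10a/16a chromosome.

Parsimony is a model/results pair:

```python
>>> from karyophy import MaxParsimony, pitheciinae_fixture
>>> results = MaxParsimony(pitheciinae_fixture()).fit()
>>> print(results.summary())
Maximum parsimony (exhaustive search)
=============================================
Taxa                     5
Characters               23
Topologies examined      15
Most parsimonious trees  1
Tree length (s)          19
Min steps (m)            17
Max steps (g)            26
Consistency index (CI)   0.895
Retention index (RI)     0.778
Homoplasy index (HI)     0.105
MP tree 1: ((BAR,CAP),(CCR,CUT),PIR);
>>> bs = results.bootstrap(n_replicates=500, seed=1)
>>> results.annotated_newick({"BAR", "CAP"}, bs)
'((BAR,CAP)98,((CCR,CUT)66,PIR)98);'
```

The single most parsimonious tree groups CCR and CUT as sister taxa and
places PIR basal within the subfamily — the matrix contains exclusive
CCR+CUT synapomorphies (the 5a1/5a2 fission, the 20/15/14 fusion, the
acrocentric 5/7a form) and no character grouping PIR with CUT, so
rooting on the outgroups yields `((BAR,CAP),(PIR,(CCR,CUT)))` with the
bootstrap percentages shown on the internal nodes.

## Command line

Every stage is a subcommand of the `karyophy` tool:

```sh
karyophy count --map src/karyophy/data/hsa_pir.tsv
karyophy associations --map src/karyophy/data/hsa_ccr.tsv
karyophy search --use-fixture --outgroup BAR --outgroup CAP
karyophy pipeline --outdir out/            # all three bundled maps + matrix
```

`pipeline` writes per-map synteny and association TSVs, the matrix
(NEXUS + TSV), all MP trees (Newick), a statistics table, a
bootstrap-annotated rooted tree and a run report. One `--seed` flag
(fixed default) governs all randomness; reruns with the same
configuration and seed are byte-identical.

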