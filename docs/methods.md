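# Methods

## Homology maps and what a "signal" is

A homology map records one painting experiment as a set of target
chromosomes, each carrying an ordered list of probe-homologous segments.
The counting unit throughout is the hybridisation signal: one table
location equals one signal, *even when its positional qualifier names a
compound span*. Two qualifier grammars occur in the source tables and
are treated differently:

* `proximal q + p` — one contiguous block spanning the centromere: one
  signal, one token in the chromosome's form label;
* `proximal p-distal q` paired with `distal p-proximal q` on the same
  chromosome — the interleaved layout left by a pericentric inversion
  inside an association: still one signal per probe, but two tokens each
  in the form label, which therefore reads `16/10/16/10`.

This is the only reading under which the published haploid signal
totals (32 for human probes on PIR, 33 on CCR, 28 for *S. oedipus*
probes on CCR) and the inverted-association form are simultaneously
consistent, so it is fixed as a package invariant and asserted in the
tests.

Sex chromosomes are excluded from autosomal totals; a signal from an
autosomal probe on the Y-autosome composite (the X1X2Y system of
*Cacajao*, male 2n = female 2n − 1) counts as one autosomal-probe
signal, but the composite is reported separately from the autosomal
association list. Within-chromosome segment order is taken from the
positional qualifiers where stated and from table order otherwise; no
order-dependent conclusion is drawn beyond what the qualifiers support.

## Association detection and ancestral matching

A target chromosome is association-bearing when its form has at least
two tokens drawn from at least two signals (two different probes, or the
same probe interleaved twice). Matching a catalogue form (e.g. `10a/16a`)
against a detected association uses token *multisets* — order-insensitive,
since `15/14` and `14/15` denote the same association — with sub-segment
letters compared only when both sides carry them, because the painting
tables do not resolve sub-blocks the way the ancestral catalogue does.
Under this rule the inverted `16/10/16/10` chromosome still carries the
ancestral `10a/16a`, which is how the inversion is interpreted in the
comparative literature.

One consequence worth stating: the PIR map contains nine
association-bearing chromosomes, of which exactly six match the
ancestral Platyrrhini catalogue; published summaries quote the six
ancestral ones. `detect_associations` applies the same uniform rule to
every map (nine in CCR under human probes, five under SOE probes) and
the "six" is recovered as the ancestral-matching subset.

## Character coding

Characters are strictly binary (presence 1 / absence 0, `?` unknown):
one column per discrete chromosome form or elementary rearrangement
product. Rows of the rearrangement table that bundle several events are
decomposed into one character each. Where a form-presence and a
rearrangement-presence encoding would be equivalent, derived states are
coded as the rearrangement and ancestral retentions as the form.

The bundled 5-taxon matrix (PIR, CCR, CUT + outgroups BAR, CAP) is a
documented reconstruction, not the study's own supplementary matrix
(which is accepted via `from_nexus`/TSV whenever available, and whose
exact 44-character content is not guessed). Its columns are: the three
subfamily synapomorphies (fusion 2a/10b, acrocentric 15/14, acrocentric
19) plus the Callicebus-shared 16a/10a/16a/10a inversion; three CCR+CUT
synapomorphies (fission 5a1+5a2, fusion 20/15/14, acrocentric 5/7a —
the last included because the 5/7a homologue is described as derived
acrocentric in both CCR and CUT but ancestral biarmed in PIR, and
without it the two CCR+CUT columns exactly tie the two PIR+CCR columns
and the search returns two trees); two PIR+CCR shared derived forms
(acrocentric 7b, acrocentric 12); the six ancestral retention characters;
and eight per-taxon autapomorphies. Every column's `source` note states
what it encodes.

Outgroup polarity is a switchable policy: `ancestral` (default) codes
outgroups 0 for derived forms and 1 for ancestral retentions — the
standard cladistic convention; `unknown` codes all outgroup cells `?`.

## Parsimony engine

Fitch small parsimony for unordered binary characters, computed by the
bottom-up union/intersection pass on the tree re-rooted at an arbitrary
leaf (the score is rooting-invariant; this is asserted against a
brute-force enumeration of all internal labellings in the tests). `?`
is treated as the full state set, so missing data never costs a step —
the behaviour of standard parsimony software.

Exhaustive search enumerates every unrooted binary topology exactly once
by stepwise leaf addition in canonical order ((2n−5)!! topologies,
verified for n = 4..8), refusing more than 10 taxa; heuristic searches
are out of scope. Identical character columns are collapsed to weighted
patterns before scoring, and a running best-length bound prunes the
per-pattern loop.

Statistics follow the standard definitions: m = Σ(observed states − 1),
g = Σ min(n₀, n₁) over all characters *including parsimony-uninformative
autapomorphies* (the convention under which a 44-character matrix of 45
steps prints CI 0.978, RI 0.909, HI 0.022 — reproduced algebraically in
the tests). Degenerate cases: an all-constant matrix gets CI = RI = 1,
HI = 0; g = m with s > m leaves RI undefined (NaN with a warning).
Reported values are rounded half-up to three decimals; exact floats are
kept on the results object.

Outgroup rooting places the root on the edge separating a monophyletic
outgroup; a non-monophyletic outgroup roots on the edge of maximum
outgroup/ingroup separation, with a warning. The bootstrap resamples
characters with replacement (same count), searches each replicate
exhaustively, and lets the k tied MP trees of a replicate contribute 1/k
each to bipartition tallies — unbiased under ties. Replicate r draws
from the deterministic substream (seed, r), so support tables are
bit-reproducible. Majority-rule consensus keeps bipartitions with
frequency above the threshold (≥ 0.5, hence mutually compatible).

## Synthetic data

Characters evolve by a symmetric two-state flip with a per-branch
*probability* (not a rate) — deliberately minimal, sufficient for
recovery testing, and exactly computable: the test suite checks the
simulated fraction of variable columns against a full enumeration of
per-branch flip patterns. Karyotypes evolve from a default 22-autosome
ancestral construction embedding the six catalogue associations (a
package convention, not a scientific claim). Event counts per branch are
Poisson with configurable mean; event types are drawn by weight and
operands uniformly over applicable choices, resampling an inapplicable
draw up to 10 times before skipping it. Reversals and convergence are
allowed on purpose, so homoplasy (CI < 1) genuinely occurs. No event
creates or destroys an ancestral segment; conservation is asserted after
every event. The simulator does not model breakpoint reuse, chromatin
context or realistic rate variation, so passing recovery tests show the
inference machinery is sound — not that real karyotype evolution is this
clean.

## Recovery experiments

A run "recovers" the generating topology when that topology is among the
most-parsimonious trees; the stricter unique-MP-tree fraction and the
mean Robinson–Foulds distance are reported alongside. The lenient
definition is the meaningful one at low information content: on a
5-taxon tree with 30 characters and per-branch flip probability 0.05, a
dataset carries on average only ~3 parsimony-informative characters, so
exact ties among topologies are routine and unique recovery is
structurally rare (measured 0.39). Under the lenient definition the same
condition yields ~0.82; with enough informative characters (200
characters at p = 0.1, ≥ 20 informative per run) the generating topology
is the unique MP tree in ≥ 95% of seeded runs, which is the regime where
a parsimony analysis of real chromosomal characters operates.

## Problem sizes and defaults

The bundled analyses are small by nature: 22 probe autosomes per map, 23
characters across 5 taxa, 15 topologies per search. Bootstrap defaults
to 1000 replicates in the library, 200 in the pipeline command, 500 in
the acceptance script; recovery experiments use 200 runs. The CLI's
default seed is fixed (not time-based) so default runs reproduce
byte-identically.
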