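# Methods

This note documents the models, conventions and numerical choices behind
`airrbench`, and what the synthetic benchmark does and does not establish
about real repertoire data.

## The benchmarking problem

Antibody heavy-chain reads are annotated by aligning them to a germline
reference of V, D and J gene segments and extracting the CDR3 (the
hypervariable loop between the conserved V-gene cysteine and J-gene
tryptophan). Tools differ in three largely independent ways: (i) the
germline reference they ship or accept, (ii) the alignment/annotation
algorithm, and (iii) output conventions (allele vs gene names, CDR3 with or
without anchors). `airrbench` separates these factors: reference content is
compared directly; conventions are removed by harmonization; and
algorithmic accuracy is measured on simulated reads whose originating
germline is known.

## Germline comparison and change tracking

Reference sets are compared by exact string identity at the subgroup,
gene, allele and nucleotide-sequence level. The multi-set comparison is an
exclusive-region (Venn/UpSet) decomposition; the headline "shared"
percentage is the all-sets region divided by the union of items across the
compared sets, rounded to integer percent. When any compared set lacks
allele designations, comparison at gene level is the meaningful common
denominator.

Change logs carry five event categories: gene removal, gene addition,
allele addition, sequence change and metadata change (name or descriptors
change but not the sequence). Interval statistics use fractional weeks
(days/7); percentiles are empirical nearest-rank (no interpolation), chosen
for exact reproducibility across numeric environments. "Changes per
update" counts events at each release after the first, the first record
being the baseline state.

Genes published under different names but carrying byte-identical
sequences are grouped by a synonym map; the canonical name is the
lexicographically smallest in the group, and canonicalization is
idempotent. At gene level the grouping is transitive through shared allele
sequences. Canonicalizing both the true and the assigned gene before
comparison prevents such duplicates from being counted as false mishits.

## Harmonization and the preprocessing cascade

All CDR3s are normalized to the *core* convention: anchored inputs must
begin with C and end with W, which are stripped; records violating the
declared convention are left unchanged and reported, never silently
altered. Calls are canonicalized through the synonym map and reduced to
gene names when gene granularity is requested.

The filter cascade runs in a fixed order: non-IgH locus, stop codon,
out-of-frame, unproductive flag, orphon-gene primary call, absent/short
CDR3 (≤ 4 aa), singleton CDR3, deduplication to unique CDR3s. Each removed
record is attributed to the *first* rule that rejects it, so per-rule
counts depend on rule order while the final output never does; the order
is fixed so reports are comparable across runs. "Productive" is the
tool's own flag once stop-codon and frame failures have already been
removed; tools lacking a flag effectively derive it from those two.

The singleton rule is abundance-aware: each record contributes its AIRR
`duplicate_count` (default 1), and deduplication aggregates the counts
onto the retained record. This makes the cascade idempotent — re-filtering
an already-filtered table removes nothing — and preserves frequency
information, so Top-N selection (ties broken lexicographically for
determinism) can operate on deduplicated tables.

## Accuracy metrics

A gene *alignment* is the first gene of the call list; a *mishit* is an
alignment to any gene other than the read's known originating germline,
compared at gene level. The cumulative frequency is K/N where N counts
only records carrying a call of that gene type — reads without a call are
reported in the confusion matrix's "no call" column and in alignment
counts, not as mishits. Per-subgroup rows are keyed by the *true* gene's
subgroup (where do errors originate), so subgroup W and X sum exactly to
the cumulative K and N. Percentages are reported at one decimal and
compared at two in tests.

Per-read CDR3 discrepancy between two tools distinguishes reads whose two
annotations have identical V/D/J assignments but different CDR3s
(annotation-algorithm differences) from reads where the gene assignments
differ too (alignment differences), each as a fraction of the common input
set.

## CDR3 similarity networks

Unique CDR3 amino-acid strings are nodes; links join pairs at Levenshtein
distance exactly 1 (unit-cost substitution, insertion, deletion; identical
strings are one node, never a link). The distance-≤1 predicate is an
early-exit scan — length difference > 1 is impossible; equal lengths allow
one mismatch; lengths differing by one require a single skipped character
— and is property-tested against a general edit-distance implementation.
Network construction compares all pairs with length-bucket pruning (an
optimization only; tested link-for-link against the all-pairs oracle).

The average degree 2L/N classifies a repertoire: below 0.5 diverse, above
0.5 polarized, exactly 0.5 reported as "boundary". Sub-networks — CDR3
subsets shared between tools — are scored by the mean degree of their
nodes *in the full parent network*, so links to non-shared CDR3s still
count and the same subset can score differently in different tools'
networks; an induced-subgraph variant (links internal to the subset only)
is available behind a flag but is not the default reading. Degree
agreement between tools over shared CDR3s uses Pearson's r and Kendall's
tau-b (tie-corrected, since degree vectors are heavily tied); a constant
vector leaves both undefined and is reported as missing rather than NaN.

## Synthetic data model

The simulator emulates clonally structured heavy-chain repertoires with
exact record counts: `n_base` founder rearrangements plus `n_mutated`
hypermutated descendants.

* **Germlines.** Random nucleotide sequences with IMGT-like names
  (1–3 alleles per gene). V genes end in a conserved TGT (cysteine) codon
  and J genes begin with TGG (tryptophan), making junction extraction
  well defined. Optional synonym pairs give two V gene names an identical
  sequence. Precondition: disjoint pairs require 2·n_synonyms ≤ n_v.
* **Founders.** Random V/D/J choice, random N-region nucleotides with the
  junction kept in frame and redrawn until stop-free; CDR3 lengths fall in
  roughly 4–17 aa, centred near 10.
* **Hypermutation.** Substitutions only — no indels — so mutated CDR3s stay
  within small edit distance of their founder, which is what gives expanded
  clones dense distance-1 neighbourhoods. Each descendant picks its parent
  uniformly from the clone's existing members (a uniform random recursive
  tree, mimicking lineage-tree simulators) and acquires
  max(1, Poisson(`mutation_rate`)) substitutions; the default rate of 3
  per generation reflects moderate per-division SHM load. A fraction 0.25
  of substitutions is targeted at the junction interior, reflecting the
  concentration of hypermutation in CDRs; junction anchor codons are
  conserved. A substitution creating a junction stop codon marks the read
  unproductive.
* **Composition.** `diverse` allocates mutants uniformly over founders
  (ratio 2 mutants per base at preset scale); `polarized` allocates by a
  rank power-law with exponent 1.5 (ratio 5), producing a few very large
  clusters. Full-scale presets are 100 000/200 000 and 20 000/100 000; the
  shipped analyses use 1 000/2 000 and 200/1 000, which preserve the
  regime behaviour at interactive runtimes.
* **Annotator emulation.** Per read and gene type, the assigned gene
  differs from truth with the profile's mishit probability (uniform redraw
  among the other genes) or per a targeted confusion pair; granularity
  controls allele suffixes, the CDR3 convention controls anchors, and
  reads can be dropped or have their productive flag flipped. All
  generators are pure functions of their arguments including the seed.

Why the two compositions separate at the 0.5 threshold: after
preprocessing, a diverse repertoire's unique CDR3s are dominated by
founder CDR3s of small clones, whose one-off mutant variants are removed
as singletons — the network is nearly edgeless (average degree ≈ 0.2–0.3
at the shipped sizes). In a polarized repertoire the large clones generate
CDR3 variants that recur along the lineage tree, survive the singleton
filter, and sit one amino acid from their parent variant — chains and
stars that push the average degree to ≈ 0.9–1.4.

## What the synthetic benchmark does not show

The generator emulates clonal structure and substitution-driven CDR3
similarity, not platform-specific sequencing error (homopolymer errors,
quality decay), primer/UMI artefacts, indel-bearing hypermutation, or the
biases of real annotation algorithms; emulated mishits are memoryless
draws, whereas real tools err systematically on near-identical germlines
(the confusion-pair mechanism approximates only the latter). Passing
regime separation therefore validates the analysis chain's behaviour under
the stated clonal models, not any claim about a specific tool's accuracy
on experimental data. Allele-level accuracy benchmarking is likewise out
of scope; all accuracy comparisons are at gene level.

## Degenerate inputs and tie-breaks

Empty reference FASTA parses to an empty set with a warning; fewer than
two sets cannot be intersected; a change log needs two distinct release
dates for interval statistics. Empty call lists are "no call"; absent
CDR3s are treated as length 0 and removed by the length rule. Top-N ties
break lexicographically; synonym canonicalization breaks ties by smallest
name; network links require distinct strings. Confusion-matrix rows sum
to 1 within 1e-9. All percentages use plain rounding at the stated
precision.
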