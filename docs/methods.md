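# Methods

## The benchmark construction problem

Evaluating homology search tools requires a gold standard: pairs of
proteins whose homology status is known with near-certainty.  Structural
and domain-family databases provide a workaround for the fact that shared
ancestry is not directly observable.  `pmdabench` builds such gold
standards from **protein multi-domain architectures (PMDAs)** — the
ordered sequence of domain family identifiers along a protein, considered
at the clan/superfamily level where a grouping is defined:

* two proteins are **homologous** (benchmark sense) when their effective
  architectures are identical position by position;
* they are **non-homologous** when they share no effective identifier in
  any order;
* every other pair is **ambiguous** and excluded from evaluation.

Using multi-domain proteins rather than isolated structural domains keeps
linkers, disordered segments and low-complexity regions in the test
sequences, which is where false-positive similarity arises in genome-scale
practice.

## Architecture construction

Domain annotations enter as per-protein hit tables (1-based inclusive
residue intervals, one of three schemes: `pfam`, `superfamily`, `gene3d`).
For each protein and scheme:

1. hits are sorted by start (ties: end, then family ID) — overlapping hits
   are kept, and only the interval *union* is used for coverage;
2. family IDs are replaced by clan/superfamily IDs where the scheme's clan
   map defines one; unmapped families are their own group;
3. under the `pfam` scheme, consecutive identical effective IDs whose
   family type is *repeat* or *motif* are collapsed to one instance,
   because repeat copy numbers are highly variable between homologs;
4. the protein is discarded if any run of ≥ `max_unassigned_run`
   (default **50**) consecutive residues is covered by no hit — a guard
   against incompletely annotated (often disordered) sequences.  Terminal
   tails count.  The discard fires at *exactly* 50, i.e. at
   `run >= threshold`;
5. architectures shorter than `min_domains` (default **2**) after mapping
   and collapsing are discarded — a single shared domain cannot separate
   full-length homology from chance domain sharing.

Disabling the coverage filter (`filter_enabled=False`, CLI
`--no-unassigned-filter`) reproduces the benchmark variant that retains
proteins with long unannotated regions; it writes a parallel artifact set.

## Pair sampling

Sampling avoids biasing the benchmark toward highly populated families.
For each distinct architecture, up to
`proteins_per_genome_per_architecture` (default **2**) proteins are drawn
uniformly without replacement from each genome, and *all* unordered pairs
among the drawn proteins — within and across genomes — become positives,
covering a range of evolutionary distances.  Negatives are drawn per
anchor architecture until they match its positive count: one protein from
the anchor, one from a uniformly chosen architecture whose identifier set
is fully disjoint from the anchor's (rejection sampling with global
deduplication; quota shortfalls are logged, never silently absorbed).
A single seeded `numpy` Generator drives all sampling; the seed is in the
run metadata.

## Scoring

Each pair is scored in a 1-to-1 query-vs-database setup through a uniform
adapter contract.  Only the best HSP's bit score is used, with no merging
of hit fragments.  Pairs for which a tool reports nothing at all — even
with maximally inclusive reporting thresholds — receive a **proxy score of
0 bits** and are never predicted homologous at any E-value cutoff.

The built-in reference scorer is an exact local Smith–Waterman alignment
(BLOSUM62, affine gaps) computed by `biotite`'s C implementation.  Gap
convention: a gap of length L costs `gap_open + (L−1)·gap_extend` with
defaults open 11, extend 1.  Raw scores convert to bits via the
Karlin–Altschul form `bits = (λ·raw − ln K)/ln 2` with λ = 0.267,
K = 0.041 (standard gapped BLOSUM62 constants), clamped at 0 so the proxy
is always the minimum, and `E = m·n·2^(−bits)` for query/database lengths
m, n.  These constants make the built-in scorer emit the same score type
as external tools; they are not fitted to anything.

External tools plug in per pair through `ExternalToolAdapter` (temporary
single-record FASTA files, free-form flag templates) with tabular-output
parsers for the 12-column BLAST layout (`blast_tab`, `fasta_m8`,
`usearch_b6`) and HMMER's per-domain table (`hmmer_domtbl`, using the
per-domain score and independent E-value).  A missing executable aborts a
run; a per-pair crash is recorded as not-found and the run continues.

## Evaluation

**Tie-aware ROC.**  Pairs are ranked by bit score descending.  Each
maximal run of equal scores containing p positives and n negatives is
rendered as a single straight segment to (FP+n, TP+p): the exact
expectation of the step curve over random orderings of the tie, so tied
positives and negatives are evenly distributed and no ordering artifact is
introduced.  Proxy pairs all sit at 0 bits and form (part of) the final
tie run; genuinely scored 0-bit alignments fall in the same run, an
ambiguity accepted and recorded here.  Note the polyline is the mean of
the step curve in *area*; pointwise, the expected TP at the j-th false
positive inside a tie run is p·j/(n+1), slightly below the segment.  The
polyline's vertices are exact under every tie ordering.

**AUCn.**  The headline statistic is the area under the TP-vs-FP polyline
truncated at the first `n_cutoff` false positives (default **1000**),
integrated exactly by trapezoids and normalized by `n_eff·P` with
`n_eff = min(n_cutoff, N)` — the standard truncated-ROC normalization
under which perfect separation scores 1.0 and a label-independent constant
scorer 0.5.  The `n_eff` fallback matters for desk-scale runs where
N < 1000.

**E-value sweep.**  At each cutoff a pair is predicted homologous iff an
alignment was found and its E-value is ≤ the cutoff.  TP+FN and FP+TN are
invariant across cutoffs; recall is non-decreasing as the cutoff loosens.

**Congruence.**  Every sampled pair is re-labelled under all three
schemes; pairs where either protein lacks an architecture in a scheme are
*uncovered* there.  For each ordered scheme pair (A, B), restricted to
pairs covered in both, the A-homologous pairs are tabulated by their
B-label as counts and percentages (two decimals).  At least one pair must
be covered by all three schemes.

## The synthetic proteome generator

The generator emulates the statistical structure the benchmark assumes —
it is the package's test bed, not a biological simulator.  It produces
domain families with consensus sequences, clans grouping half of them
(`clan_assignment_fraction=0.5`, 3 clans over 12 families), repeat-type
flags (`repeat_family_fraction=0.25`), 8 distinct architectures of 2–3
domains, 3 mock genomes × 3 proteins per architecture, and every
annotation/mapping table plus FASTA the pipeline reads.

Key modelling choices, with rationale:

* **Motif-scale domain units, 15–35 residues.**  The mutation-rate sweep
  {0.05, 0.3, 0.6} (each copy mutated independently from consensus, so
  pairwise divergence is roughly double) must span the discriminative
  regime of a local aligner: with units of 40+ residues, even 0.3 leaves
  ~50% pairwise identity over long blocks and the benchmark saturates at
  AUC 1.0 for the lower two rates.  At 15–35 residues the homologous
  signal at intermediate divergence sits near the random-local-alignment
  background — the remote-homology twilight zone a challenging benchmark
  must probe.  Verified monotone (AUC1000 at 0.05 > 0.3 > 0.6) across ten
  arbitrary seeds.
* **Uniform amino-acid background; substitutions uniform over the other
  19; single-residue indels (rate 0.03/residue) with geometric extension.**
  The simplest process that exercises affine-gap alignment; no
  phylogenetic realism intended or claimed.
* **Linkers of 5–30 random residues; with probability 0.1 per linker a
  20–60-residue homopolymer or dipeptide run is inserted, never
  annotated.**  These low-complexity insertions are deliberate
  false-positive bait and also exercise the ≥50-residue coverage filter
  (a linker plus insertion frequently exceeds it, so the default fixture
  discards a realistic fraction of proteins).
* **`scheme_divergence` (default 0.1) is the only cross-scheme
  disagreement source.**  With probability 0.1 per family, the second and
  third schemes split a family out of its clan or merge an unassigned
  family into an existing clan — granularity changes only, never order
  changes, and never clans invented in a clanless scheme.  Per-protein
  repeat copy-number variation (`repeat_expansion_probability`) would be a
  second, independent disagreement source (collapsing is Pfam-only, so
  expanded copies make Pfam-homologous pairs ambiguous under the other
  schemes); it therefore defaults to 0 and is exercised explicitly in
  tests.  At `scheme_divergence=0` all three schemes agree on every pair
  by construction, which the congruence table must report as 100.00%
  homologous in every off-diagonal cell.
* **Architectures are deduplicated at the effective clan level** of the
  base scheme: two family tuples with one effective architecture are the
  same PMDA.

What passing tests on this generator do **not** show: performance on real
proteomes (real domain families are neither uniform-random nor
independent, real linkers are compositionally biased, and real annotation
schemes disagree in richer ways than split/merge), nor anything about the
relative accuracy of published search tools.

## Numerical and procedural choices

* Benchmark sizes: the default fixture yields ≈ 70 proteins and ≈ 100
  positive + 100 negative pairs per run; every test and the acceptance
  script complete in seconds on one core.
* Determinism: one `numpy` Generator per sampling stage seeded from the
  run seed; positives drawn before negatives from the same stream; all
  TSV/JSON artifacts are written without timestamps and with sorted keys,
  so same-seed reruns are byte-identical.
* Query/database direction: protein_a is the query by default; a
  `direction="max"` option scores both orientations and keeps the better
  bit score.  The direction is recorded in run metadata.
* Degenerate inputs: ROC evaluation refuses inputs without both classes;
  congruence refuses label tables with no fully covered pair; empty hit
  lists yield a `no_annotation` discard rather than an error.
* Tie-breaks: overlapping hits order by (start, end, family ID);
  architecture and genome iteration is sorted everywhere a selection is
  made, so RNG consumption is platform-independent.

## Known limitations

* The built-in scorer's Karlin–Altschul constants are nominal, not
  estimated from the score distribution; its E-values are comparable
  within a run but not calibrated against BLAST's.
* Proxy-scored pairs and genuine 0-bit alignments share one tie run.
* Negative sampling may reuse proteins across pairs (a config flag
  enforces protein-disjoint negatives if wanted).
* Discontinuous/nested domains are linearized by start order only.
* No significance testing between tools' AUC values.
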