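# Methods

## The problem

Shotgun metagenomic reads translated and aligned against a large peptide
reference (blastx/DIAMOND style) routinely hit many references equally well:
protein families share highly conserved domains, so a 250 bp read drawn from
inside such a domain cannot distinguish the family members on alignment
score alone. Accepting every hit inflates the apparent protein coding
sequence (CDS) catalogue of a community with false positives; keeping only
uniquely mapping reads discards genuinely present CDS whose every read falls
in a shared region. This package resolves each read pair to a single
reference CDS by combining two sources of information the alignments alone
do not use: the *evenness* of coverage along each candidate reference, and
the *sample-wide* weight of evidence for each reference.

## The model

Let `score(q, s)` be the probability-like weight that read (pair) `q`
originates from reference `s`, kept normalised so that
`sum_s score(q, s) = 1` for every `q`.

1. **Coverage evenness pre-filter.** The coverage depth `CD` of a reference
   is the number of candidate reads overlapping each amino-acid position.
   A reference is discarded when

       CD_STD / CD_Mean > threshold        (default threshold = 1.0)

   where the mean and the *population* standard deviation are taken over
   the full reference length, zeros included — the vector is the complete
   coverage profile, not a sample, and uncovered positions are evidence of
   absence. A reference recruited only through a conserved domain shows a
   domain-shaped plateau and nothing else; for a binary profile covering a
   fraction `p` of positions the CV is `sqrt((1-p)/p)`, so the default
   threshold removes references with less than half their length covered,
   however deep the pile-up. The decision is scale-free. Boundary cases
   are kept: the filter fires only on strictly greater CV.

2. **Score initialisation.** `score(q, s) = bitscore(q, s) / sum_s'
   bitscore(q, s')` over `q`'s surviving candidates.

3. **Iterative reweighting and pruning.** Each iteration computes the
   sample-wide subject weight `W(s) = sum_q score(q, s)`, multiplies each
   score by its subject's weight, renormalises per query, and prunes every
   candidate whose score falls below `prune_ratio` (default 0.5) times its
   query's maximum; survivors are renormalised again. The per-query maximum
   survives by construction, so no query ever loses all candidates to
   pruning, and uniquely mapping reads are fixed points. Iteration stops
   when a round prunes nothing or after `max_iterations` (default 10)
   rounds. This is an expectation-maximisation-style update: deeply and
   evenly covered references accumulate weight and absorb ambiguous reads,
   starving their decoys.

4. **Final assignment and re-filter.** Each query is assigned its highest
   scoring surviving subject (ties broken by higher `W(s)`, then
   lexicographically smallest subject id — determinism, not biology). The
   evenness filter is then re-applied to the deduplicated one-subject-per-
   read alignments with unit weights; reads whose assigned subject fails
   this re-check are reported as unassigned rather than silently dropped.

The relative prune threshold is a design choice: an absolute threshold
would interact with candidate-set size, while `prune_ratio x max` is
scale-free and reproduces the observed gradual culling over a handful of
iterations. Whether bitscores should re-enter the update at every iteration
(rather than only at initialisation) is an open modelling question; here
bitscore information enters once, at initialisation, and all later
reweighting is driven by the sample-wide weights. The final evenness
re-check runs once; it does not trigger further reassignment rounds.

### Input normalisation

The two mates of a pair share one query identity (mate suffixes `/1`,
`/2`, ` 1:...` are stripped), so a pair is resolved jointly: one candidacy
— and hence one score — per (query, subject) pair, carried by the
highest-bitscore row when an aligner reports several local alignments.
Coverage, however, counts *reads*: every collapsed row's subject interval
(typically the two mates') contributes to the coverage vector, each at the
pair's weight. Keeping only the winning mate's interval would be wrong in
a subtle way: bitscores of equally perfect alignments differ by residue
composition, which is spatially correlated along a reference, so the
"best" mate is systematically drawn from one side of the fragment and the
evenness statistic gets distorted. For the same reason, exact bitscore
ties in deduplication are broken by a CRC of the row rather than input
order (never systematically mate 1).

Per-read acceptance of near-best alignments uses an additive band on the
percent-identity scale: a record survives when its identity is within
`tolerance_pct` percentage points of its query's best (0 = top-hit rule,
ties kept; 10 = the "top-10" rule). A relative bitscore band is available
as a configuration switch (`metric="bitscore"`).

## Synthetic data

The generator produces communities with the structure that causes
multi-mapping in real references, at desk scale:

* **Homolog families**: peptides sharing an identical conserved domain with
  member-unique flanks drawn independently (pairwise flank identity at the
  ~5% random-alphabet baseline). Community CDS fall in three classes —
  *twins* (a near-full-length decoy homolog, domain ~90% of the length: no
  read maps uniquely, the case where unique-hit mapping fails), *domain
  families* (a ~35% domain shared with decoys: decoys recruit reads but
  only over the domain, the case the evenness filter targets), and
  unrelated singletons. Decoys live in the reference database but in no
  genome.
* **Depths**: per-genome depth = `min(100, 10^N(log10(5), 1))` — a
  log-normal whose *median* is 5x with a 1-log10 SD and a 100x cap. The cap
  sits 2 SD above the centre, which is only coherent on the log10 scale;
  an alternative mean-parameterisation is exposed as a flag.
* **Reads**: paired-end 250 bp from normal(1000, 300) bp fragments
  truncated to the template; pair counts follow
  `round(depth x length / (2 x read_length))`; optional uniform
  substitution errors (no indels, constant quality strings — error
  robustness, not platform realism, is what these tests need). Reads from
  whole genomes (CDS embedded in random intergenic spacers) carry the label
  of the CDS they overlap most, with a one-codon minimum.
* **Emulated translated aligner**: six-frame translation, stop-free
  segments seeded through an exact 6-mer index, Smith-Waterman scoring
  (BLOSUM62, gap -11/-1) with standard Karlin-Altschul bit conversion, one
  best row per mate-reference pair. Scoring is exact, so an error-free
  read's true origin is always among its top hits and domain-internal reads
  tie exactly across family members — slightly cleaner than a production
  aligner's heuristics, which is the point: correctness of the downstream
  algorithm can be asserted against known truth.

What the generator does *not* emulate: real error/quality profiles, indels,
strain-level variation, GC or positional coverage bias, and reference
databases many orders of magnitude larger than the community. Passing tests
therefore demonstrate algorithmic correctness under controlled homology
structure, not field performance against UniRef-scale references.

### Template-length caveat

Fragments are clipped to their template. When a template is barely longer
than the fragment distribution (e.g. a ~1.35 kb CDS under 1000±300 bp
fragments), nearly every fragment straddles the whole template: mates pile
at the two ends and the template middle is never sequenced, so even a truly
present CDS looks uneven. This is a physical artifact of fragment ≈
template, not a property of the algorithm. The controlled within-CDS
scenario therefore draws 500±150 bp fragments on its 450-aa templates so
paired reads tile the CDS; the whole-genome path keeps the standard
1 kb ± 300 geometry because genomes are tens of kilobases.

## Benchmarking harness

Detected and true CDS sets are each clustered at 90% global amino-acid
identity (greedy longest-first, CD-HIT style; identity is
`1 - edit_distance / max(len)`), then compared all-vs-all by local
alignment. A detection is **TP** when it and a truth are mutual best hits,
**DUP** when it aligns to a truth (>= 50% identity over >= 50% of the
shorter sequence; both floors configurable — below them a pair "does not
align") without being that truth's best detected hit, **FP** when it aligns
to no truth; truths without a TP partner are **FN**. Classification runs on
cluster representatives. Metrics: sensitivity `TP/(TP+FN)`, positive
predictive value `TP/(TP+FP)`, uniqueness `TP/(TP+DUP)`; empty denominators
are reported as undefined (`null`), never 0. Depth stratification uses
(0, 5] and (5, inf) bins on the true CDS's depth; FP detections carry no
true depth and enter every bin's PPV unchanged.

Two mapping baselines put the filter's numbers in context: *all-hits*
(any reference with one accepted alignment is "detected") and *unique-hits*
(references with at least one read whose accepted candidate set is a
singleton).

## Problem sizes and numerical choices

The controlled multi-mapping scenario uses 3 true CDS (450 aa), 120
error-free read pairs each, and 10 decoy homologs per CDS with domain
fractions cycling through {0.4, 0.6, 0.75} — small domains die on evenness,
large ones only through iterative pruning. The community benchmark uses 20
genomes x 8 CDS (150–400 aa, ~230 kb of genome sequence, ~10⁴ read pairs),
sized so a full simulate-align-filter-evaluate cycle completes in well
under a minute on one CPU while preserving every qualitative feature of the
design (log-normal depths with the 100x cap, 250 bp pairs from 1 kb
fragments, decoy-bearing homolog families). Score updates are pure float64
array arithmetic; per-query normalisation is exact to ~1e-15 and asserted
at 1e-9 in tests. All randomness flows through seeded numpy generators;
the core filter itself contains no randomness at all.

## Known limitations

* The evenness filter penalises very low coverage: whenever the reads of a
  sparsely covered CDS jointly span less than half its length (for a
  roughly binary profile, CV = sqrt((1-p)/p) > 1 when p < 1/2), the CDS is
  discarded regardless of how genuine the reads are, so sensitivity at the
  lowest depths is structurally limited (visible in the 0–5x stratum of
  the benchmark).
* Greedy 90% clustering is order-dependent in principle (length sort with
  id tie-break makes it deterministic here) and uses an edit-distance
  identity, which slightly undercounts identity for gappy pairs.
* The emulated aligner reports one local alignment per mate-reference pair
  (no multiple HSPs) and does not model frameshifts.
* Baseline definitions operate on the same accepted alignment set as the
  filter; results compare strategies, not specific external tools.
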