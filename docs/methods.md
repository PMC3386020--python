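# Methods

## Problem and model

Homology-based annotation transfers a functional description from database
sequences detected by BLAST to an uncharacterised query. The failure mode
this package addresses is that the *order* of a BLAST hit list is a poor
guide to annotation quality: the best-scoring hits may be unannotated,
misannotated, or described with uninformative boilerplate, while the
correct wording is spread over lower-scoring relatives. The method
therefore (1) normalises hit descriptions, (2) partitions hits into
functionally consistent clusters using two independent annotation schemes
(free-text DEs and GO term sets), and (3) lets clusters vote with their
bit-score mass through a word/sentence scoring scheme. The prediction is
the highest-scoring description; lower-priority clusters are reported as
alternative functions.

The scoring model assumes each hit contributes independent evidence
proportional to its bit score. This is the standard weighted-voting
assumption and it fails when database composition is biased (many
near-identical depositions of one favourite protein); using a
redundancy-reduced database mitigates that, and the package deliberately
does not attempt frequency recalibration.

## Pipeline stages and parameters

1. **Hit filtering** (`blast_io.FilterPolicy`). Defaults: bit score ≥ 50,
   alignment length ≥ 30 columns, self-hits removed, one (best-bit) row
   per query-subject pair. Identity and coverage thresholds (percent,
   default 0 = off) are strict-removal: a hit *below* the threshold is
   dropped, a hit exactly at it survives. Coverage of side *s* is
   `100 · alignment_length / length(s)`; tabular BLAST output does not
   carry the ungapped subject span, so gapped alignment columns are the
   numerator (documented choice; the alternative subject-coordinate span
   is not available in this format). The genome preset uses identity 40 /
   subject coverage 50 — values suited to removing spurious hits in
   whole-proteome runs. An optional relative-bit-score filter divides each
   hit's bit score by the query's self-hit bit score.

2. **DE processing** (`de_processing`). Tokenisation is lowercasing +
   whitespace splitting + edge-punctuation stripping (interior hyphens
   kept). The shipped stop list has the 21 entries as published — including
   a duplicated "possible" and the phrase "similar to" — and matching uses
   the deduplicated set, the phrase as a two-token unit. The
   infrequent-word rule activates at ≥ 10 hits: words with total occurrence
   count 1 across the hit list are removed, but only from descriptions
   that also contain a word of count ≥ 2 (a description made entirely of
   rare words is left alone). Counting total occurrences equals counting
   per-DE presence here, because a count-1 word occurs in exactly one DE.
   EC-number trimming exists as a reusable operation but is applied only
   in the annotation-comparison (mLD) path, not in tool mode.

3. **GO annotations** (`ontology`). Direct GAF assignments (NOT-qualified
   rows excluded) are filtered by evidence policy — `all` (default) or
   `experimental_and_computational` (EXP/IDA/IPI/IMP/IGI/IEP +
   ISS/ISO/ISA/ISM/IGC/IBA/IBD/IKR/IRD/RCA) — then pooled over the three
   ontologies and closed over `is_a` ancestors *including* the root.
   `part_of` edges are not followed: "ancestor" is read conservatively as
   the subsumption hierarchy. Annotations with < 3 distinct terms are not
   accepted for linking (they sit too close to the root to be
   discriminative). The ≥ 3 threshold is exposed (`min_go_terms`).

4. **Clustering** (`clustering`). Stage 1 links hits with identical
   processed DE text. Stage 2 computes each element's representative GO
   set — by default the accepted annotation of its highest-bit member
   (`top_hit` mode; bit ties break lexicographically by subject id for
   reproducible runs), optionally the union over every *n*-th member
   (`every_nth`, user-definable step; union equality is the comparison) —
   and merges elements whose representative sets are *exactly equal*.
   Exact-set equality is transitive, so grouping by the set realises the
   transitive closure; the synonym-rescue behaviour emerges with no extra
   mechanism. Elements without an accepted annotation stay singleton
   clusters, and with no GO data at all the output degrades to the DE
   partition.

5. **Scoring** (`scoring`). Word and sentence scores as in the README; the
   final score averages word and sentence support. The published wording
   ("an average of the word and sentence scores") is read as the two-term
   mean of (mean per-word score, S_k) — default `two_term`; the plausible
   alternative that pools all word scores and S_k into one average is
   shipped as `flat`. Ranking is deterministic: descriptions by descending
   final score, ties by bit-score sum then text; clusters by their best
   description the same way. The report keeps three levels: best DE,
   ranked clusters (alternative functions), and per-cluster description
   tables (frequency, bit sum, best hit id — the pre-GO-clustering view).
   Both processed and raw best-hit descriptions are reported, since either
   may be the more useful label downstream.

## The modified Levenshtein distance

Two annotations X and Y are normalised (EC codes trimmed, lowercased,
tokenised, rejoined with single spaces). If either has no tokens, or only
stop-list tokens, the distance is defined as 1.0 — note the stop set is
used only for this emptiness test; surviving stop-word tokens still take
part in the distance. Otherwise each side is expanded into word elements
x1…xn plus consecutive-pair elements "xi xi+1" (n + n−1 elements). The
cross pair with the smallest element distance is recorded and removed
together with every element on either side sharing a word with it; this
repeats until one side is exhausted, after which each *remaining word
element* of the other side is scored against the empty string (pair
elements are excluded by default to avoid counting each character twice; a
switch restores the inclusive behaviour). The distance is the recorded sum
divided by the character length (spaces included) of the longer normalised
annotation, capped at 1. Character length — not word count — is the
normaliser; word count would contradict the ≈ 0.25 reference value for the
four-word example pair.

The element distance comes from a global alignment scored +2 match / −1
substitution / −1 gap: the returned count is the number of non-match
columns, **minimised over all maximum-score alignments** (lexicographic
dynamic programme on score, then column count). Minimising over co-optimal
alignments — rather than fixing a traceback preference — makes the count
well-defined and symmetric; a preference-based traceback can return either
7 or 9 for "oxygenase" vs "neuronal" depending on which co-optimal path it
walks, and only 7 reproduces the ≈ 0.25 reference value. Under this scoring
the count can exceed the unconstrained unit-cost edit distance (e.g.
"cryptochrome" vs "photolyase": 10 vs 9) because maximising match count is
worth extra gap columns; the two coincide on identical, fully dissimilar
and one-empty pairs, which the test suite checks against an independent
unit-cost oracle.

Greedy pair selection breaks ties by smallest combined element length, then
by the lexicographically smallest *unordered* pair, preserving
mld(X,Y) == mld(Y,X). The metric remains blind to synonyms and to
specificity differences — "GyrA" vs "DNA gyrase, subunit A" scores badly,
"DNA polymerase" matches both "DNA polymerase I" and "DNA polymerase IV" —
which is why the evaluation harness treats it as a graded error measure
rather than a correctness test.

## Evaluation harness

Competing predictors: `top_hit` (best-bit non-self hit), `top_informative`
(best-bit hit whose description contains no uninformative words),
`most_common`, `max_bitsum`, `word_score` (the scoring scheme on a single
all-hit group), and the full pipeline. The single-hit methods return raw
descriptions; the pooling methods operate on processed descriptions, since
frequency and word mass are only meaningful after normalisation. Ties break
randomly under a caller-supplied seed; per-method streams are derived from
(seed, crc32(method)), so the harness is bit-reproducible.

`go_restrict` partitions hits by exact accepted-GO-set equality and hands a
method only the largest part when it has ≥ 5 members (size ties: higher bit
sum, then seeded random); otherwise all hits — the control used to show
that GO grouping alone does not explain the pipeline's advantage.

Per query, the distance of each prediction to the gold description is
standardised against the mLDs of all hit descriptions:
z = −(x − μ)/σ, positive = better than a random pick from the hit list.
σ is the population SD (the hit list *is* the population being sampled);
queries with σ = 0 are excluded from Z statistics. Aggregation over queries
uses sample SD (ddof = 1).

The filter sweep tests the 36 combinations of identity and subject-coverage
thresholds {0, 20, 40, 60, 80, 100}%, recording per query the minimum
(ideal prediction), median (expected) and maximum (worst-case) mLD over
surviving hit descriptions, aggregated as mean ± SD over queries with ≥ 1
hit; the count of covered queries is reported per cell. Even-count medians
are the mean of the central pair. Circular-reference removal drops hits
whose subject creation date is on or after the query's annotation date;
undated hits are kept (and logged), since absence of a date is not evidence
of circularity.

## Synthetic benchmark generator

`fixtures.generate` emits a mutually consistent file set (BLAST tabular
with an `sdate` column, OBO, GAF 2.2, gold TSV, query FASTA) from a single
seeded model, so the same seed yields byte-identical files and regenerating
one file cannot drift from the others. Each query has a hidden gold
description (2–4 words from a 66-word vocabulary free of stop-list terms)
and a gold GO set (a leaf of a generated three-root DAG plus its
ancestors). Hits are classed as optimal (gold DE), misspelled (k character
edits), uninformative-only, or decoy (other functions), with bit scores
drawn uniformly and independently of class — deliberately: hit order
carries no information about correctness, which is the regime the method
is designed for.

Defaults mirror the characterisation of curated bacterial benchmark data:
Poisson-distributed hit counts with mean 72, 15% optimal-DE hits, 45%
optimal-GO hits (roughly three-fold the DE rate). Values not fixed by that
characterisation were chosen once as realistic: 5% misspelled (2 edits),
10% uninformative-only, 50% of decoy hits GO-annotated, bit scores
uniform on [50, 400].

What the generator does **not** emulate: sequence evolution (bit scores
and identities are drawn, not computed from alignments), correlated errors
between DE and GO schemes, database redundancy bias, and real GO DAG
topology (multiple parents). Passing tests therefore demonstrate the
correctness of the algorithmic machinery under controlled conditions, not
field accuracy on real databases.

Named scenarios construct specific regimes: `majority-gold` (bit-weighted
majority provably gold: 20 fixed hits, 60% optimal, decoys with unique
vocabulary, so the gold cluster's ≥ 600-bit mass always beats any ≤ 400-bit
singleton), `top-hit-misleading` (the three best-bit hits are decoys),
`remote-only` (informative hits confined to 40–50% identity, uninformative
hits above 60%, so an aggressive identity filter destroys the signal),
`synonym-rescue` (the gold description appears in two word orders whose
elements are guaranteed one gold-GO member each, forcing a GO-mediated
merge), and `no-go` (empty GAF).

## Problem sizes and numerical choices

Tests and example runs use scaled-down benchmarks (6–20 queries for
structural checks, 100 queries × 20 hits for the recovery scenario), chosen
to keep the suite fast while leaving every code path exercised; the
generator's condition parameters are identical at any scale. Sentence
scores over a query sum to 1 within 1e-12 (pure summation, no rescaling).
All randomness flows through numpy Generators seeded from user-supplied
integers; no global RNG state is touched. Degenerate inputs are defined
explicitly: empty hit lists yield "no prediction" reports, empty
descriptions cannot reach the scorer (dropped earlier), σ = 0 queries are
excluded from Z statistics rather than scored as infinite.

## Known limitations

- The mLD inherits every blindness of string metrics to synonymy and
  specificity; the evaluation design (graded distances, Z-scores, human
  review for genome runs) reflects that.
- Exact GO-set equality is a hard linking criterion; a single extra term
  prevents a merge. The every-nth pooling mode softens this only partially.
- The scoring scheme has no defence against database redundancy bias.
- `part_of` closure and per-ontology (rather than pooled) GO comparison are
  conceivable variants that are not implemented.
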