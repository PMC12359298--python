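# Methods

`crossmir` chains five stages, each a pure function over explicit data
types, from two disease-specific differential-miRNA tables to a ranked
pathway list and an approved-drug shortlist. This note documents the
model behind each stage, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical and design
choices made where the design was genuinely open.

## Stage 1 — shared-miRNA screen

Each table row is one study-level report: a miRNA observed up- or
downregulated in cases versus controls in one study of one disease.
The screen is direction-only vote counting: a miRNA is *shared up* iff
it has at least one up report in each disease and no down report
anywhere (symmetric for *shared down*). A miRNA observed in both
diseases with mixed directions is excluded, with within-disease
discordance diagnosed before cross-disease discordance; a miRNA seen in
one disease only is a non-candidate, not a conflict, and is kept in the
provenance output but nowhere else. Fold changes and p-values are
carried but never weighted — the rule is deliberately conservative (one
discordant study vetoes a candidate) and performs no meta-analytic
pooling.

Matching is exact on normalized names (species prefix stripped, case
folded, `-3p`/`-5p` arm suffixes preserved, since distinct arms are
distinct mature miRNAs). A `collapse_families` option drops the arm
suffix and votes at family level; it defaults off because family-level
grouping conflates arms with potentially different regulation.

The module also hosts the JBI case-control risk-of-bias classifier
(score 0–10: ≤ 4 high, 5–7 moderate, ≥ 8 low risk). It annotates study
quality only; the screen never weights votes by it.

## Stage 2 — strong-evidence targets

Interaction records are tiered by their `support_type` label; only
`Functional MTI` (case-insensitive, whitespace-trimmed, otherwise
strict — `Functional MTI (Weak)` fails) counts as strong evidence. The
label is the tier authority; free-text experiment methods are not
parsed. Per direction, target sets are unions over the shared miRNAs'
strong records. A shared miRNA with no strong record — absent from the
table, or present only with weak records — is reported as `missing`,
because silence would be indistinguishable from an empty target set.
`collect_targets` refuses unfiltered input outright (a contract error)
rather than filtering quietly. The per-miRNA map flattens to a
deduplicated `(miRNA, gene, direction)` edge list, stably sorted, for
external graph tools.

## Stage 3 — over-representation and transactions

For a query of n genes in a universe of N, a pathway of K genes and an
overlap of k, the p-value is the upper hypergeometric tail P(X ≥ k)
(scipy's `hypergeom.sf(k-1, N, K, n)`); k = 0 gives exactly 1.
Benjamini–Hochberg (via statsmodels) adjusts across the whole library.
Query genes outside the library's gene union are dropped with a logged
count. The universe defaults to that union and is overridable by an
explicit integer (backgrounds of web enrichment services are
library-dependent; the choice is surfaced rather than hidden).

Pathways pass with adjusted p ≤ `adj_threshold` (default 1e-5, a
first-class parameter) unless their name contains an exclusion keyword
(case-insensitive substring; shipped defaults: infection(s), rheumat-,
cancer, carcinoma, leukemia, melanoma, cell cycle). The keyword list is
the reproducible surrogate for a manual curation step: transparent,
logged, configurable. Retained pathways, ordered by ascending adjusted
p with ties on the id, become transactions. A transaction carries the
*overlap* genes (query ∩ pathway) by default — the mined combinations
should be combinations of the disease-linked targets, not of bystander
pathway members — with `transaction_genes = full` preserving the
alternative reading.

## Stage 4 — Apriori mining and pathway ranking

Support of an itemset is the fraction of transactions containing every
one of its genes, stored as an exact `Fraction` (count /
n_transactions). All comparisons happen on rationals; half-up rounding
to 4 decimals occurs only when a report table is written, so float
drift can never reorder or misclassify a result. Two thresholds govern
the level-wise search:

* `min_item_support` prunes single genes — 0.40 on the down branch,
  0.15 on the up branch. These floors apply to *genes*, not to larger
  sets: down-branch pair supports near 0.25–0.29 coexist with the 0.40
  floor only under gene-level pruning.
* `min_rule_support` (0.01) is the floor for itemsets of size ≥ 2 and
  for association rules.

Level k candidates join frequent (k−1)-sets sharing k−2 items and are
discarded if any (k−1)-subset is infrequent (anti-monotone pruning);
iteration stops when no candidate survives. By anti-monotonicity this
closure equals the exhaustive rule "every member gene above the gene
floor and the set above the rule floor", which is what the test oracle
enumerates. A configurable candidate ceiling guards against
pathological inputs; `max_itemset_size` is unlimited by default. Every
ordering (itemsets, rules, ranks) has a documented lexicographic
tie-break, making outputs byte-stable.

Rules A → B are emitted for every non-empty proper subset A of every
frequent itemset of size ≥ 2, with support(A∪B) ≥ 0.01; confidence is
reported but not thresholded (no confidence cut is part of the method).

Pathway ranking: each gene's *individual* support is computed over the
full, unpruned transaction set; a pathway's score is the arithmetic
mean over its own genes, and ranks are descending with ties broken by
id. The score is a mean of gene supports, not the support of the
pathway's gene set as a whole. Computing gene supports before pruning
follows the definition of the score over *all* genes of a pathway.

## Stage 5 — drug shortlist

The `top_k` (default 4) highest-supported single genes per direction —
their union, six genes under the default conditions — are queried
against the drug table. A record survives iff the gene was queried, the
drug is approved (a boolean input column, not an external lookup) and
its interaction score is strictly greater than `min_score` = 0.10; a
score of exactly 0.10 is excluded. Scores are snapshot-static inputs.

## Synthetic data: what is emulated, and how

The generator's defaults are the study conditions, not tuning knobs:
two signatures of 124 and 286 distinct miRNAs; 21 shared (10 up, 11
down, anchored by let-7b, miR-34c-5p and miR-132-3p); four conflicting
miRNAs covering both exclusion subtypes; four shared miRNAs absent from
the interaction table (miR-1260a, miR-3176, miR-671-3p, miR-181c-3p —
their direction is not constrained by the emulated tables, so two are
assigned to each direction; half carry only weak records, half none);
233 up / 337 down target genes; 265 down / 243 up pathway transactions;
and the published FDA-approved drug catalog for AKT1, MAPK1, MAP2K1,
RAF1, HRAS and PIK3R1, padded per gene with a boundary record at
exactly 0.10, one below, and a high-scoring unapproved drug.

Joint gene counts are planted exactly by a block construction. For
planted itemsets with target counts c(C), dedicated-transaction counts
follow by Möbius inversion over the containment order:
`block(C) = c(C) − Σ block(D) for planted D ⊋ C`, each block holding
exactly C among planted genes. Then support(C) = c(C) holds exactly
whatever the blocks' gene overlaps, and every non-planted subset's
count is the derived block sum, also exact. Negative blocks mean the
requested supports are jointly infeasible and raise an error. The
default planted counts reproduce every published 4-decimal pair/triple
support (e.g. 78/265 = 0.2943 for MAP2K1/MAPK1 on the down branch,
69/243 = 0.2840 for MAP2K1/RAF1 on the up branch). The count of
transactions holding *all four* planted genes of a branch is not
published; inclusion–exclusion bounds it to [34, 52] on the down
branch, and 40 is fixed on both branches — any feasible value
reproduces every published number while keeping all unpublished combos
below the 0.2000 print floor.

Solo transactions lift each planted gene to a per-direction support
floor (0.45 down, 0.30 up) so it survives gene-level pruning, as the
real high-frequency genes do; they cannot disturb joint counts. Filler
genes pad every transaction to at least `min_tx_genes` (4) members —
keeping each pathway's enrichment far below the 1e-5 cut against a
20 000-gene universe — and are drawn round-robin from the direction's
own target pool (never from planted genes) under a hard per-gene cap of
0.10 support, well below every planted value, so spurious itemsets
cannot reach the gene floors or mask planted combinations. One
filler-free flagship transaction holds a branch's full planted gene set
(`PID_TCR_RAS_PATHWAY` down, `BIOCARTA_ECM_PATHWAY` up); since every
other transaction mixes in below-average filler supports, the flagship
tops the mean-support ranking by construction. Keyword-named decoy
pathways (significant but excluded) and background pathways (never
significant) exercise the two filter predicates; their counts are
chosen so retained transactions equal the planted set exactly.

One global seed spawns four independent RNG sub-streams (study tables,
interactions, pathways, drugs), so reparameterizing one generator never
perturbs another, and a fixed config yields byte-identical outputs.

What the generator does *not* emulate: realistic fold-change/p-value
distributions (plausible ranges only), study-level heterogeneity,
pathway-size distributions of real libraries, or database-snapshot
drift. Passing tests therefore demonstrate correctness of the
computation and exact recovery of planted structure — not robustness of
the conclusions to real-data noise, nor the counts any particular
database snapshot would yield (target and pathway totals drift with
snapshots; they are validated on synthetic truth only).

## Numerical choices and degenerate inputs

Supports, confidences and pathway scores: exact rationals end-to-end;
4-decimal (scores: 6-decimal) half-up rendering at the reporting
boundary only. Hypergeometric p-values are floats clamped to (0, 1].
Decimal parsing is locale-independent; comma separators are rejected.
Empty queries, empty transaction databases, empty itemsets, score or
threshold ranges outside their domains, and inconsistent planted
supports all raise typed validation errors rather than propagating
empty results. An empty direction (no shared miRNAs or no significant
pathways) flows through the pipeline as explicitly empty outputs and is
marked as such in the summary.

## Problem sizes

The default end-to-end run — the acceptance workload — is 430 study
observations, ~670 interaction records, a 524-pathway library over a
20 000-gene universe, and 508 mining transactions; it completes in a
few seconds. The mining oracle cross-check enumerates all itemsets on
200 random databases of up to 12 genes × 10 transactions, the scale at
which exhaustive enumeration is itself trustworthy.

## Known limitations

* The enrichment stage is a plain hypergeometric test; it does not
  reproduce web services' combined or rank-based scores, and the
  keyword exclusion approximates a manual curation judgement.
* Strong evidence is trusted from the `support_type` label alone.
* The consistency screen's veto rule is sensitive to single discordant
  studies and ignores effect sizes and study quality by design.
* Mined supports quantify co-occurrence across *enriched* pathways;
  they are conditional on the enrichment cut and carry no significance
  measure of their own.
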